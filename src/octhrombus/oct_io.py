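"""Polar OCT data model and file I/O.

The polar domain is canonical throughout the package: frames are stored as
A-line-major matrices (rows = A-lines over one catheter rotation, columns =
depth samples, index 0 at the catheter). Depth of sample ``j`` is
``j * axial_pitch_mm``. Scan conversion to Cartesian display coordinates is
deliberately out of scope.

Readers and writers cover:

* multi-page TIFF (or a directory of PNG pages) intensity stacks with a JSON
  metadata sidecar (``axial_pitch_mm``, ``catheter_offset``, optional
  ``patient_id`` and ``frame_ids``);
* per-frame ROI masks as single-channel images, multi-page stacks, or
  run-length-encoded JSON;
* tidy CSV statistic tables that round-trip float64 values exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: 8-connectivity structuring element used for fragment labelling; matches
#: free-hand tracing of contiguous blobs.
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)

_REQUIRED_SIDECAR_KEYS = ("axial_pitch_mm", "catheter_offset")

#: Fixed column order for statistic tables (documented in the README).
STATISTICS_COLUMNS = (
    "patient_id",
    "frame_id",
    "channel",
    "statistic",
    "value",
    "included_pixels",
    "threshold_mm",
)


@dataclass(frozen=True)
class PolarFrame:
    """One polar OCT frame: A-line-major intensity matrix plus calibration.

    Attributes
    ----------
    intensity
        2-D array, shape ``(n_alines, n_depth)``; native grayscale units,
        finite and non-negative.
    axial_pitch_mm
        Depth spacing per sample in millimetres (> 0).
    catheter_offset
        First depth index of tissue-usable signal; columns before it belong
        to the catheter interior.
    frame_id, patient_id
        Free-form identifiers carried through the pipeline.
    """

    intensity: np.ndarray
    axial_pitch_mm: float
    catheter_offset: int
    frame_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity)
        if arr.ndim != 2:
            raise FormatError(f"intensity must be 2-D, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise FormatError("intensity contains non-finite values")
        if (arr < 0).any():
            raise FormatError("intensity contains negative values")
        if not self.axial_pitch_mm > 0:
            raise ConfigurationError("axial_pitch_mm must be > 0")
        offset = int(self.catheter_offset)
        if not 0 <= offset < arr.shape[1]:
            raise ConfigurationError(
                f"catheter_offset {offset} outside depth range [0, {arr.shape[1]})"
            )
        object.__setattr__(self, "intensity", arr)
        object.__setattr__(self, "catheter_offset", offset)
        object.__setattr__(self, "axial_pitch_mm", float(self.axial_pitch_mm))

    @property
    def n_alines(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[1]

    def depth_mm(self, j: int | np.ndarray) -> float | np.ndarray:
        """Physical depth of sample index ``j`` (0-based)."""
        return np.asarray(j) * self.axial_pitch_mm


@dataclass(frozen=True)
class RegionMask:
    """Boolean ROI membership congruent with a :class:`PolarFrame`.

    ``fragment_labels`` assigns a positive integer to each 8-connected
    fragment (0 = background); it is derived automatically when the mask is
    built through :meth:`from_array`.
    """

    member: np.ndarray
    frame_id: str = ""
    fragment_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        member = np.asarray(self.member, dtype=bool)
        if member.ndim != 2:
            raise FormatError(f"mask must be 2-D, got shape {member.shape}")
        object.__setattr__(self, "member", member)
        if self.fragment_labels is not None:
            labels = np.asarray(self.fragment_labels)
            if labels.shape != member.shape:
                raise FormatError("fragment_labels shape differs from member shape")
            object.__setattr__(self, "fragment_labels", labels)

    @classmethod
    def from_array(cls, arr: np.ndarray, frame_id: str = "") -> "RegionMask":
        """Build a mask from any array; nonzero pixels become members and
        8-connected fragments are labelled."""
        member = np.asarray(arr) != 0
        labels, _ = ndimage.label(member, structure=EIGHT_CONNECTED)
        return cls(member=member, frame_id=frame_id, fragment_labels=labels)

    @property
    def n_members(self) -> int:
        return int(self.member.sum())

    @property
    def n_fragments(self) -> int:
        if self.fragment_labels is None:
            return 0
        return int(self.fragment_labels.max())

    def fragment_sizes(self) -> dict[int, int]:
        """Pixel count per fragment label (label -> count)."""
        if self.fragment_labels is None:
            return {}
        labels, counts = np.unique(self.fragment_labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts) if l != 0}


@dataclass(frozen=True)
class ObserverReading:
    """One visual six-stage grade (1 = purely white ... 6 = purely red)."""

    patient_id: str
    observer_id: str
    session: int
    tas: int

    def __post_init__(self) -> None:
        if int(self.tas) not in range(1, 7):
            raise ConfigurationError(f"tas must be in 1..6, got {self.tas}")
        object.__setattr__(self, "tas", int(self.tas))
        object.__setattr__(self, "session", int(self.session))


# ---------------------------------------------------------------------------
# stack / sidecar I/O


def _read_stack(stack_path: str | Path) -> list[np.ndarray]:
    path = Path(stack_path)
    if path.is_dir():
        pages = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
        return [np.asarray(iio.imread(p)) for p in pages]
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        return [arr]
    if arr.ndim == 3:
        return [arr[i] for i in range(arr.shape[0])]
    raise FormatError(f"unsupported stack dimensionality {arr.ndim} in {path}")


def read_sidecar(sidecar_path: str | Path) -> dict:
    """Load and validate a JSON metadata sidecar."""
    sidecar = json.loads(Path(sidecar_path).read_text())
    for key in _REQUIRED_SIDECAR_KEYS:
        if key not in sidecar:
            raise ConfigurationError(f"sidecar {sidecar_path} missing required key {key!r}")
    return sidecar


def read_pullback(stack_path: str | Path, sidecar_path: str | Path) -> list[PolarFrame]:
    """Read an intensity stack plus its sidecar into a list of frames.

    One :class:`PolarFrame` per page, page order preserved. An empty stack
    yields an empty list (with a warning).
    """
    sidecar = read_sidecar(sidecar_path)
    pages = _read_stack(stack_path)
    if not pages:
        logger.warning("empty stack %s: returning no frames", stack_path)
        return []
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise FormatError(f"pages of {stack_path} have mismatched shapes: {sorted(shapes)}")
    patient_id = str(sidecar.get("patient_id", ""))
    frame_ids = sidecar.get("frame_ids") or [f"frame_{i:03d}" for i in range(len(pages))]
    if len(frame_ids) != len(pages):
        raise FormatError(
            f"sidecar lists {len(frame_ids)} frame_ids but stack has {len(pages)} pages"
        )
    return [
        PolarFrame(
            intensity=page,
            axial_pitch_mm=float(sidecar["axial_pitch_mm"]),
            catheter_offset=int(sidecar["catheter_offset"]),
            frame_id=str(fid),
            patient_id=patient_id,
        )
        for page, fid in zip(pages, frame_ids)
    ]


def write_pullback(
    frames: Sequence[PolarFrame],
    stack_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    """Write frames as a multi-page TIFF plus JSON sidecar.

    Integer-valued intensities are stored as uint16 so that
    ``read_pullback(write_pullback(frames))`` round-trips exactly; other
    data is stored as float32.
    """
    if frames:
        data = np.stack([f.intensity for f in frames])
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.uint16)
        elif np.allclose(data, np.round(data)) and data.max(initial=0) < 65536:
            data = np.round(data).astype(np.uint16)
        else:
            data = data.astype(np.float32)
        sidecar = {
            "axial_pitch_mm": frames[0].axial_pitch_mm,
            "catheter_offset": frames[0].catheter_offset,
            "patient_id": frames[0].patient_id,
            "frame_ids": [f.frame_id for f in frames],
        }
    else:
        data = np.zeros((0, 1, 1), dtype=np.uint16)
        sidecar = {"axial_pitch_mm": 0.005, "catheter_offset": 0, "patient_id": "", "frame_ids": []}
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # zero-page stacks are deliberate
        tifffile.imwrite(stack_path, data, photometric="minisblack")
    Path(sidecar_path).write_text(json.dumps(sidecar, sort_keys=True, indent=2) + "\n")


# ---------------------------------------------------------------------------
# masks


def _mask_from_rle(payload: Mapping) -> np.ndarray:
    shape = tuple(payload["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in payload["runs"]:
        flat[start : start + length] = True
    return flat.reshape(shape)


def read_mask(mask_path: str | Path, frame: PolarFrame) -> RegionMask:
    """Read a single-frame ROI mask (image or RLE JSON) for ``frame``.

    Nonzero pixels become members; 8-connected fragments are labelled.
    Raises :class:`FormatError` on any dimension mismatch with the frame.
    """
    path = Path(mask_path)
    if path.suffix.lower() == ".json":
        arr = _mask_from_rle(json.loads(path.read_text()))
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse an accidental channel axis
            arr = arr[..., 0]
    if arr.shape != frame.intensity.shape:
        raise FormatError(
            f"mask shape {arr.shape} does not match frame shape {frame.intensity.shape}"
        )
    return RegionMask.from_array(arr, frame_id=frame.frame_id)


def write_mask_stack(masks: Sequence[RegionMask], path: str | Path) -> None:
    """Write masks as a multi-page uint8 TIFF (255 = member)."""
    data = np.stack([m.member for m in masks]).astype(np.uint8) * 255
    tifffile.imwrite(path, data, photometric="minisblack")


def read_mask_stack(path: str | Path, frames: Sequence[PolarFrame]) -> list[RegionMask]:
    """Read a multi-page mask stack aligned page-for-page with ``frames``."""
    pages = _read_stack(path)
    if len(pages) != len(frames):
        raise FormatError(f"mask stack {path} has {len(pages)} pages for {len(frames)} frames")
    out = []
    for page, frame in zip(pages, frames):
        if page.shape != frame.intensity.shape:
            raise FormatError(
                f"mask page shape {page.shape} does not match frame "
                f"{frame.frame_id} shape {frame.intensity.shape}"
            )
        out.append(RegionMask.from_array(page, frame_id=frame.frame_id))
    return out


# ---------------------------------------------------------------------------
# tabular output


def write_statistics_table(
    records: Iterable[Mapping],
    path: str | Path,
    fieldnames: Sequence[str] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write tidy statistic records as CSV.

    Values are formatted with ``%.17g`` so float64 round-trips bit-exactly
    (and therefore losslessly at 15 significant digits). An empty record
    list produces a header-only file; ``fieldnames`` fixes the column order
    (defaults to :data:`STATISTICS_COLUMNS` for empty input).
    """
    records = list(records)
    if fieldnames is None:
        fieldnames = list(records[0].keys()) if records else list(STATISTICS_COLUMNS)
    df = pd.DataFrame.from_records(records, columns=fieldnames)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def read_statistics_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_statistics_table` (skips ``#`` lines)."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def read_observer_table(path: str | Path) -> list[ObserverReading]:
    """Read observer readings from CSV (patient_id, observer_id, session, tas)."""
    df = read_statistics_table(path)
    return [
        ObserverReading(
            patient_id=str(r.patient_id),
            observer_id=str(r.observer_id),
            session=int(r.session),
            tas=int(r.tas),
        )
        for r in df.itertuples()
    ]
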