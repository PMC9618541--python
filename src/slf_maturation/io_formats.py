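"""Readers and writers for the on-disk formats the pipeline touches.

Streamlines travel as TCK (the ``mrtrix tracks`` dialect: a text header
terminated by ``END``, then float triplets with NaN-triplet separators
between streamlines and a single Inf triplet terminating the body).
Scalar maps and ROI label maps are NIfTI-1, handled by nibabel.  Gradient
tables are read in either the FSL (separate bval/bvec files) or the MRtrix
(single four-column file) dialect.

Coordinate convention: streamline coordinates are ALWAYS world millimetres
in memory.  Conversion to voxel indices happens only inside ROI membership
tests and metric sampling, never at I/O time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import nibabel as nib
import numpy as np
import yaml

from .errors import CorruptFileError, FormatError, GradientError

__all__ = [
    "VolumeImage",
    "Tractogram",
    "GradientScheme",
    "read_tck",
    "write_tck",
    "read_volume",
    "write_volume",
    "read_gradients",
    "read_yaml",
]

TCK_MAGIC = "mrtrix tracks"

# b-values within this tolerance (s/mm^2) belong to the same shell
SHELL_TOLERANCE = 50.0


@dataclass
class VolumeImage:
    """A 3-D scalar grid (metric map or integer ROI label map) plus its
    voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3-D or 4-D data, got {self.data.ndim}-D")
        if min(self.data.shape[:3]) < 1:
            raise ValueError("each spatial axis must have length >= 1")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (n, 3) to continuous voxel indices (n, 3)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        index = np.atleast_2d(np.asarray(index, dtype=float))
        return index @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class Tractogram:
    """An ordered collection of streamlines (world-mm polylines)."""

    streamlines: list
    header: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError("each streamline must be an (n, 3) array")
            if s.shape[0] < 2:
                raise ValueError("each streamline needs >= 2 points")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit diffusion-encoding directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise GradientError("bvecs must be (n, 3)")
        if len(self.bvals) != len(self.bvecs):
            raise GradientError(
                f"bvals ({len(self.bvals)}) and bvecs ({len(self.bvecs)}) "
                "have different lengths"
            )
        if np.any(self.bvals < 0):
            raise GradientError("negative b-value")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > SHELL_TOLERANCE
        if np.any(norms[dw] < 1e-8):
            raise GradientError("zero direction on a diffusion-weighted volume")
        # normalise non-zero directions; b=0 rows may legitimately be (0,0,0)
        nz = norms > 1e-8
        self.bvecs = self.bvecs.copy()
        self.bvecs[nz] = self.bvecs[nz] / norms[nz, None]

    def __len__(self) -> int:
        return len(self.bvals)

    def shells(self, tol: float = SHELL_TOLERANCE) -> list:
        """Unique nominal b-values, grouped within ``tol`` s/mm^2, ascending."""
        centres: list[float] = []
        counts: list[int] = []
        for b in self.bvals:
            for i, c in enumerate(centres):
                if abs(b - c) <= tol:
                    # running mean keeps the centre representative
                    centres[i] = (c * counts[i] + b) / (counts[i] + 1)
                    counts[i] += 1
                    break
            else:
                centres.append(float(b))
                counts.append(1)
        return sorted(centres)

    def shell_indices(self, b: float, tol: float = SHELL_TOLERANCE) -> np.ndarray:
        return np.nonzero(np.abs(self.bvals - b) <= tol)[0]

    @property
    def b0_indices(self) -> np.ndarray:
        return self.shell_indices(0.0)


# ---------------------------------------------------------------------------
# TCK


def _parse_tck_header(raw: bytes) -> tuple[dict, int]:
    """Parse the text header; return (header dict, byte offset of body)."""
    first_nl = raw.find(b"\n")
    first = raw[: first_nl if first_nl != -1 else len(raw)].decode(
        "ascii", errors="replace"
    )
    if not first.startswith(TCK_MAGIC):
        raise FormatError(
            f"not a TCK file: first line {first!r} (expected '{TCK_MAGIC}')"
        )
    header: dict[str, str] = {}
    pos = first_nl + 1
    offset = None
    while pos < len(raw):
        nl = raw.find(b"\n", pos)
        if nl == -1:
            nl = len(raw)
        line = raw[pos:nl].decode("ascii", errors="replace").strip()
        pos = nl + 1
        if line == "END":
            break
        if ":" in line:
            key, _, value = line.partition(":")
            header[key.strip()] = value.strip()
    else:
        raise CorruptFileError("TCK header not terminated by END")
    if "file" in header:
        try:
            offset = int(header["file"].split()[-1])
        except (ValueError, IndexError):
            raise CorruptFileError(f"malformed 'file' field: {header['file']!r}")
    if offset is None:
        raise CorruptFileError("TCK header lacks a 'file' field")
    return header, offset


_TCK_DTYPES = {
    "Float32LE": "<f4",
    "Float32BE": ">f4",
    "Float64LE": "<f8",
    "Float64BE": ">f8",
}


def read_tck(path) -> Tractogram:
    """Read an MRtrix ``.tck`` streamline file.

    Raises :class:`FormatError` if the magic line is missing and
    :class:`CorruptFileError` if the body lacks the Inf terminator.  A
    mismatch between the declared ``count`` and the actual number of
    streamlines is reported as a warning and the actual count is used.
    """
    raw = Path(path).read_bytes()
    header, offset = _parse_tck_header(raw)
    dtype_name = header.get("datatype", "Float32LE")
    if dtype_name not in _TCK_DTYPES:
        raise FormatError(f"unsupported TCK datatype {dtype_name!r}")
    body = np.frombuffer(raw[offset:], dtype=_TCK_DTYPES[dtype_name])
    if body.size % 3 != 0:
        raise CorruptFileError("TCK body length is not a multiple of 3")
    triplets = body.reshape(-1, 3).astype(float)
    if triplets.shape[0] == 0 or not np.all(np.isinf(triplets[-1])):
        raise CorruptFileError("TCK body truncated: no Inf terminator")
    triplets = triplets[:-1]
    is_sep = np.all(np.isnan(triplets), axis=1)
    streamlines = []
    start = 0
    for idx in np.nonzero(is_sep)[0]:
        if idx > start:
            streamlines.append(triplets[start:idx])
        start = idx + 1
    if start < triplets.shape[0]:
        streamlines.append(triplets[start:])
    if "count" in header:
        try:
            declared = int(header["count"])
        except ValueError:
            declared = -1
        if declared != len(streamlines):
            warnings.warn(
                f"TCK count mismatch: header says {declared}, "
                f"found {len(streamlines)}; using actual count",
                stacklevel=2,
            )
            header["count"] = str(len(streamlines))
    return Tractogram(streamlines=streamlines, header=header)


def write_tck(tractogram: Tractogram, path) -> None:
    """Write Float32LE TCK readable by :func:`read_tck` and by MRtrix tools."""
    path = Path(path)
    n = len(tractogram)
    header_lines = [TCK_MAGIC]
    extra = {
        k: v
        for k, v in tractogram.header.items()
        if k not in ("datatype", "count", "file")
    }
    for key, value in extra.items():
        header_lines.append(f"{key}: {value}")
    header_lines.append("datatype: Float32LE")
    header_lines.append(f"count: {n}")
    # the 'file' field stores the byte offset of the body, which itself
    # depends on how many digits the offset takes to print
    stub = "\n".join(header_lines) + "\nfile: . "
    base = len(stub.encode("ascii")) + len("\nEND\n")
    for ndigits in range(1, 12):
        offset = base + ndigits
        if len(str(offset)) == ndigits:
            break
    header_text = stub + str(offset) + "\nEND\n"
    assert len(header_text.encode("ascii")) == offset

    chunks = []
    sep = np.full((1, 3), np.nan, dtype="<f4")
    for s in tractogram.streamlines:
        chunks.append(np.asarray(s, dtype="<f4"))
        chunks.append(sep)
    chunks.append(np.full((1, 3), np.inf, dtype="<f4"))
    body = np.vstack(chunks) if chunks else np.full((1, 3), np.inf, dtype="<f4")
    with open(path, "wb") as fh:
        fh.write(header_text.encode("ascii"))
        fh.write(body.astype("<f4").tobytes())


# ---------------------------------------------------------------------------
# NIfTI


def read_volume(path, ndim: int | None = 3) -> VolumeImage:
    """Read a NIfTI volume.

    ``ndim`` enforces the expected dimensionality (3 for metric/label maps,
    4 for DWI series, None to accept either).  Trailing singleton axes are
    squeezed before the check.  When qform and sform disagree nibabel's
    best-affine rule applies (sform preferred) and a warning is emitted.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if ndim is not None and data.ndim != ndim:
        raise ValueError(f"expected {ndim}-D volume, got {data.ndim}-D")
    hdr = img.header
    if isinstance(hdr, nib.Nifti1Header):
        sform, qform = hdr.get_sform(), hdr.get_qform()
        if (
            int(hdr["sform_code"]) > 0
            and int(hdr["qform_code"]) > 0
            and not np.allclose(sform, qform, atol=1e-4)
        ):
            warnings.warn("qform/sform disagree; using sform", stacklevel=2)
    return VolumeImage(data=data, affine=img.affine)


def write_volume(volume: VolumeImage, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    # sform only: the quaternion qform cannot represent shear exactly
    img.set_sform(volume.affine, code=2)
    img.set_qform(None, code=0)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Gradients


def _load_text_table(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(str(path), comments="#"))


def read_gradients(
    bval_path, bvec_path=None, dialect: str = "fsl"
) -> GradientScheme:
    """Read a gradient table.

    ``dialect='fsl'`` expects two files: a single-row b-value file and a
    3-row b-vector file.  ``dialect='mrtrix'`` expects one 4-column file
    (x, y, z, b) in ``bval_path`` and ignores ``bvec_path``.
    """
    if dialect == "fsl":
        if bvec_path is None:
            raise GradientError("FSL dialect needs both bval and bvec files")
        bvals = _load_text_table(bval_path).ravel()
        bvecs = _load_text_table(bvec_path)
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        elif bvecs.shape == (3, 3):
            # ambiguous 3x3: FSL convention is one row per axis
            bvecs = bvecs.T
    elif dialect == "mrtrix":
        table = _load_text_table(bval_path)
        if table.shape[1] != 4:
            raise GradientError(
                f"MRtrix gradient table needs 4 columns, got {table.shape[1]}"
            )
        bvecs, bvals = table[:, :3], table[:, 3]
    else:
        raise GradientError(f"unknown gradient dialect {dialect!r}")
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def write_gradients_mrtrix(scheme: GradientScheme, path) -> None:
    table = np.column_stack([scheme.bvecs, scheme.bvals])
    np.savetxt(str(path), table, fmt="%.10g")


def write_gradients_fsl(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.10g")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.10g")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
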