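"""Voxel geometry shared by all image containers.

Array axis order throughout the package is ``(x, y, slice, frame)``.
Slice indices are 0-based in arrays; the slice-timing formula consumes
1-based slice numbers in acquisition order, and that conversion happens in
exactly one place (:func:`caslquant.perfusion.effective_pld` callers pass
``slice_index + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VolumeGeometry:
    """In-plane and through-slice sampling of an imaging volume.

    Parameters
    ----------
    voxel_size_xy : tuple of float
        In-plane voxel size ``(dx, dy)`` in micrometres.
    slice_thickness : float
        Slice thickness in micrometres.
    n_slices : int
        Number of slices (>= 1).
    matrix : tuple of int
        In-plane matrix ``(nx, ny)``.
    """

    voxel_size_xy: tuple[float, float]
    slice_thickness: float
    n_slices: int
    matrix: tuple[int, int]

    def __post_init__(self) -> None:
        dx, dy = self.voxel_size_xy
        if dx <= 0 or dy <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        nx, ny = self.matrix
        if nx < 1 or ny < 1:
            raise ValueError("matrix dimensions must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume shape ``(nx, ny, n_slices)``."""
        return (self.matrix[0], self.matrix[1], self.n_slices)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        """Voxel size ``(dx, dy, dz)`` in millimetres (NIfTI zoom units)."""
        return (
            self.voxel_size_xy[0] / 1000.0,
            self.voxel_size_xy[1] / 1000.0,
            self.slice_thickness / 1000.0,
        )

    @classmethod
    def from_zooms_mm(cls, zooms: tuple[float, float, float], shape: tuple[int, int, int]) -> "VolumeGeometry":
        # NIfTI stores zooms as float32; round to nm so round trips are exact
        dx, dy, dz = (round(z * 1000.0, 3) for z in zooms)
        return cls(
            voxel_size_xy=(dx, dy),
            slice_thickness=dz,
            n_slices=int(shape[2]),
            matrix=(int(shape[0]), int(shape[1])),
        )
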