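"""Similarity-index fields on a regular lattice and the descriptor matrix.

At every lattice point q and for every field f the similarity index of a
molecule is A_f(q) = -sum_i w_probe * w_i,f * exp(-alpha * r_iq^2), the
Gaussian-attenuated overlap of a unit probe atom with the per-atom field
weights.  The five per-field grids are flattened into one descriptor matrix
with block scaling so the fields enter the regression on a comparable
variance footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, InputError
from .prepare import FIELD_NAMES, AlignedMolecule

BLOCK_SCALING_MODES = ("equal_variance", "none")


@dataclass(frozen=True)
class FieldConfig:
    """Lattice geometry, attenuation and probe settings."""

    spacing: float = 2.0  # Angstrom
    margin: float = 4.0  # Angstrom beyond the union bounding box
    attenuation_alpha: float = 0.3  # 1/Angstrom^2
    probe_weights: dict = dc_field(
        default_factory=lambda: {"S": 1.0, "E": 1.0, "H": 1.0, "D": 1.0, "A": 1.0}
    )
    column_drop_sigma: float = 1e-6  # minimum column SD retained
    block_scaling: str = "equal_variance"

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.attenuation_alpha <= 0:
            raise ValueError("attenuation_alpha must be positive")
        if self.block_scaling not in BLOCK_SCALING_MODES:
            raise ValueError(f"block_scaling must be one of {BLOCK_SCALING_MODES}")


@dataclass(frozen=True)
class Grid:
    """Axis-aligned regular lattice."""

    origin: np.ndarray  # (3,)
    shape: tuple[int, int, int]
    spacing: float

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> np.ndarray:
        """All lattice points, flattened in C order, shape (n_points, 3)."""
        axes = [self.origin[k] + self.spacing * np.arange(self.shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def translated(self, shift: np.ndarray) -> "Grid":
        return Grid(origin=self.origin + np.asarray(shift, float), shape=self.shape, spacing=self.spacing)


@dataclass
class FieldBlock:
    """One field's molecule x grid-point value matrix plus column bookkeeping."""

    field_name: str
    grid: Grid
    values: np.ndarray  # (n_molecules, n_points), unscaled
    kept_columns: np.ndarray  # indices into the flattened grid

    def kept_values(self) -> np.ndarray:
        return self.values[:, self.kept_columns]


@dataclass
class DescriptorMatrix:
    """Combined, block-scaled descriptor matrix with back-mapping metadata."""

    X: np.ndarray  # (n_molecules, n_kept_total), block scaling applied
    column_field: np.ndarray  # field name per column
    column_point: np.ndarray  # flattened grid index per column
    block_scale: dict[str, float]  # multiplier applied to each field block
    blocks: dict[str, FieldBlock]
    grid: Grid
    molecule_ids: list[str]

    def columns_of(self, field_name: str) -> np.ndarray:
        return np.flatnonzero(self.column_field == field_name)


def build_grid(molecules: Sequence[AlignedMolecule], config: FieldConfig) -> Grid:
    """Lattice covering the union bounding box plus the margin on every side.

    Dimension along each axis is floor(extent/spacing) + 1, extent measured
    from (min - margin) to (max + margin).
    """
    if len(molecules) == 0:
        raise InputError("cannot build a grid for zero molecules")
    all_coords = np.vstack([m.coords for m in molecules])
    lo = all_coords.min(axis=0) - config.margin
    hi = all_coords.max(axis=0) + config.margin
    extent = hi - lo
    shape = tuple(int(np.floor(e / config.spacing + 1e-9)) + 1 for e in extent)
    return Grid(origin=lo, shape=shape, spacing=config.spacing)


def similarity_index(
    molecule: AlignedMolecule,
    point: np.ndarray,
    field_name: str,
    config: FieldConfig,
) -> float:
    """Similarity index of one molecule at one point for one field."""
    point = np.asarray(point, dtype=float).reshape(1, 3)
    r2 = np.sum((molecule.coords - point) ** 2, axis=1)
    w = molecule.weights[field_name]
    probe = config.probe_weights.get(field_name, 1.0)
    return float(-probe * np.sum(w * np.exp(-config.attenuation_alpha * r2)))


def field_matrix(
    molecules: Sequence[AlignedMolecule],
    grid: Grid,
    field_name: str,
    config: FieldConfig,
) -> np.ndarray:
    """Vectorized evaluation of one field for all molecules at all points."""
    pts = grid.points()
    probe = config.probe_weights.get(field_name, 1.0)
    out = np.empty((len(molecules), grid.n_points), dtype=float)
    for i, mol in enumerate(molecules):
        d2 = cdist(mol.coords, pts, metric="sqeuclidean")
        out[i] = -probe * (mol.weights[field_name] @ np.exp(-config.attenuation_alpha * d2))
    return out


def assemble_descriptors(
    molecules: Sequence[AlignedMolecule],
    config: FieldConfig | None = None,
    grid: Grid | None = None,
) -> DescriptorMatrix:
    """Compute all five field blocks and combine them into one matrix.

    Columns with an across-molecule standard deviation below
    ``column_drop_sigma`` are dropped per field; with ``equal_variance``
    block scaling each surviving block is rescaled so its total column
    variance is 1, making per-field contribution percentages comparable.
    """
    config = config or FieldConfig()
    if grid is None:
        grid = build_grid(molecules, config)
    ids = [m.compound_id for m in molecules]

    blocks: dict[str, FieldBlock] = {}
    segments, col_field, col_point = [], [], []
    scales: dict[str, float] = {}
    for name in FIELD_NAMES:
        values = field_matrix(molecules, grid, name, config)
        sd = values.std(axis=0, ddof=0)
        kept = np.flatnonzero(sd > config.column_drop_sigma) if config.column_drop_sigma > 0 else np.arange(values.shape[1])
        blocks[name] = FieldBlock(field_name=name, grid=grid, values=values, kept_columns=kept)
        if kept.size == 0:
            scales[name] = 1.0
            continue
        block = values[:, kept]
        if config.block_scaling == "equal_variance":
            total_var = float(block.var(axis=0, ddof=0).sum())
            scale = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
        else:
            scale = 1.0
        scales[name] = scale
        segments.append(block * scale)
        col_field.append(np.full(kept.size, name, dtype=object))
        col_point.append(kept)

    if not segments:
        raise ConfigurationError("variance filter dropped every column in every field")
    X = np.hstack(segments)
    if not np.all(np.isfinite(X)):
        raise ConfigurationError("descriptor matrix contains non-finite values")
    return DescriptorMatrix(
        X=X,
        column_field=np.concatenate(col_field),
        column_point=np.concatenate(col_point).astype(int),
        block_scale=scales,
        blocks=blocks,
        grid=grid,
        molecule_ids=ids,
    )


# ---------------------------------------------------------------------------
# grid file export
# ---------------------------------------------------------------------------

_BOHR_PER_ANGSTROM = 1.0 / 0.52917721092


def write_cube(grid: Grid, values: np.ndarray, path: str | Path, comment: str = "duotox field") -> None:
    """Write a scalar grid as a Gaussian cube file (no atoms block)."""
    values = np.asarray(values, dtype=float).reshape(grid.shape)
    o = grid.origin * _BOHR_PER_ANGSTROM
    step = grid.spacing * _BOHR_PER_ANGSTROM
    lines = [comment, "scalar field on a regular lattice"]
    lines.append(f"{0:5d}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}")
    lines.append(f"{grid.shape[0]:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}")
    lines.append(f"{grid.shape[1]:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}")
    lines.append(f"{grid.shape[2]:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}")
    flat = values.ravel(order="C")
    for start in range(0, flat.size, 6):
        lines.append("".join(f"{v:13.5E}" for v in flat[start : start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_dx(grid: Grid, values: np.ndarray, path: str | Path) -> None:
    """Write a scalar grid in OpenDX format."""
    values = np.asarray(values, dtype=float).reshape(grid.shape)
    nx, ny, nz = grid.shape
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    flat = values.ravel(order="C")
    for start in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[start : start + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "field" class field')
    Path(path).write_text("\n".join(lines) + "\n")
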