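"""Bijections between the latent index grid and 1D token sequences.

Four ordering classes are provided: raster (row-major), S-curve
(boustrophedon), Hilbert (a generalized Hilbert curve valid on arbitrary
rectangles; in 3D, Hilbert within the two trailing axes and boustrophedon
across the leading axis, which keeps every consecutive pair of cells
grid-adjacent), and random permutations.  Each class can be augmented with
per-axis reflections and an axis transposition; the set of augmentations of
one class forms the model ensemble — 8 variants in 2D (4 reflection
patterns x optional transpose), 7 in 3D (identity plus the 6 single/double
axis reflections).

An ordering is stored as the permutation ``perm`` with ``perm[j]`` = the
flat (C-order) grid index visited at sequence position ``j``; the
descriptor (class, shape, flags, seed) is what checkpoints serialize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ordering",
    "raster_ordering",
    "s_curve_ordering",
    "hilbert_ordering",
    "random_ordering",
    "make_ordering",
    "ensemble_orderings",
    "apply_ordering",
    "invert_ordering",
]


@dataclass
class Ordering:
    name: str
    grid_shape: tuple[int, ...]
    perm: np.ndarray  # sequence position -> flat grid index
    descriptor: dict
    _inv: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.perm = np.asarray(self.perm, dtype=np.int64)
        d = int(np.prod(self.grid_shape))
        if sorted(self.perm.tolist()) != list(range(d)):
            raise ValueError(f"ordering {self.name!r} is not a permutation of {d} cells")

    @property
    def inverse_perm(self) -> np.ndarray:
        if self._inv is None:
            inv = np.empty_like(self.perm)
            inv[self.perm] = np.arange(self.perm.size)
            self._inv = inv
        return self._inv

    def position_of(self, coord) -> int:
        """Sequence position of a grid coordinate."""
        flat = int(np.ravel_multi_index(tuple(coord), self.grid_shape))
        return int(self.inverse_perm[flat])

    def coordinate_of(self, position: int) -> tuple[int, ...]:
        """Grid coordinate visited at a sequence position."""
        return tuple(int(v) for v in np.unravel_index(int(self.perm[position]), self.grid_shape))

    def apply(self, grid: np.ndarray) -> np.ndarray:
        if grid.shape != self.grid_shape:
            raise ValueError(f"grid shape {grid.shape} != ordering shape {self.grid_shape}")
        return grid.reshape(-1)[self.perm]

    def invert(self, sequence: np.ndarray) -> np.ndarray:
        sequence = np.asarray(sequence)
        if sequence.size != self.perm.size:
            raise ValueError(f"sequence length {sequence.size} != grid size {self.perm.size}")
        out = np.empty(self.perm.size, dtype=sequence.dtype)
        out[self.perm] = sequence
        return out.reshape(self.grid_shape)


def apply_ordering(grid: np.ndarray, ordering: Ordering) -> np.ndarray:
    return ordering.apply(grid)


def invert_ordering(sequence: np.ndarray, ordering: Ordering) -> np.ndarray:
    return ordering.invert(sequence)


# ---------------------------------------------------------------------------
# transformed-grid helper: reflections + axis transposition
# ---------------------------------------------------------------------------


def _transformed_cells(grid_shape, reflect, transpose):
    nd = len(grid_shape)
    reflect = tuple(bool(r) for r in (reflect if reflect is not None else (False,) * nd))
    if len(reflect) != nd:
        raise ValueError("one reflect flag per axis required")
    if transpose is None:
        axes = tuple(range(nd))
    elif transpose is True:
        axes = tuple(reversed(range(nd)))
    else:
        axes = tuple(transpose)
    if sorted(axes) != list(range(nd)):
        raise ValueError(f"invalid axis permutation {axes}")
    cells = np.arange(int(np.prod(grid_shape))).reshape(grid_shape)
    for ax, flag in enumerate(reflect):
        if flag:
            cells = np.flip(cells, axis=ax)
    cells = np.transpose(cells, axes)
    return cells, reflect, axes


def raster_ordering(grid_shape, reflect=None, transpose=None) -> Ordering:
    """Row-major traversal of the (reflected, transposed) grid."""
    cells, reflect, axes = _transformed_cells(grid_shape, reflect, transpose)
    return Ordering(
        name="raster",
        grid_shape=tuple(grid_shape),
        perm=cells.reshape(-1),
        descriptor={"class": "raster", "shape": list(grid_shape), "reflect": list(reflect), "transpose": list(axes)},
    )


def _snake(cells: np.ndarray) -> np.ndarray:
    """Boustrophedon traversal: odd-indexed sub-blocks visited in reverse."""
    if cells.ndim == 1:
        return cells
    parts = []
    for i in range(cells.shape[0]):
        sub = _snake(cells[i])
        parts.append(sub[::-1] if i % 2 else sub)
    return np.concatenate(parts)


def s_curve_ordering(grid_shape, reflect=None, transpose=None) -> Ordering:
    """Row-wise traversal with alternating direction (grid-adjacent steps)."""
    cells, reflect, axes = _transformed_cells(grid_shape, reflect, transpose)
    return Ordering(
        name="s_curve",
        grid_shape=tuple(grid_shape),
        perm=_snake(cells),
        descriptor={"class": "s_curve", "shape": list(grid_shape), "reflect": list(reflect), "transpose": list(axes)},
    )


def _gilbert2d(h: int, w: int):
    """Generalized Hilbert curve on an h x w rectangle.

    Recursive construction valid for arbitrary (non-power-of-two,
    anisotropic) rectangles.  Consecutive cells are grid-adjacent whenever
    a corner-to-corner Hamiltonian path exists (always when either side is
    even-split-friendly, e.g. square or even-sided grids); on some
    odd-by-even rectangles a single diagonal step is parity-unavoidable.
    Yields (row, col) pairs; on square grids the first step moves along
    axis 0.
    """

    def sgn(v):
        return (v > 0) - (v < 0)

    def walk(x, y, ax, ay, bx, by):
        w_ = abs(ax + ay)
        h_ = abs(bx + by)
        dax, day = sgn(ax), sgn(ay)
        dbx, dby = sgn(bx), sgn(by)
        if h_ == 1:
            for _ in range(w_):
                yield (x, y)
                x += dax
                y += day
            return
        if w_ == 1:
            for _ in range(h_):
                yield (x, y)
                x += dbx
                y += dby
            return
        ax2, ay2 = ax // 2, ay // 2
        bx2, by2 = bx // 2, by // 2
        w2 = abs(ax2 + ay2)
        h2 = abs(bx2 + by2)
        if 2 * w_ > 3 * h_:
            if w2 % 2 and w_ > 2:  # keep split even for parity of turns
                ax2 += dax
                ay2 += day
            yield from walk(x, y, ax2, ay2, bx, by)
            yield from walk(x + ax2, y + ay2, ax - ax2, ay - ay2, bx, by)
        else:
            if h2 % 2 and h_ > 2:
                bx2 += dbx
                by2 += dby
            yield from walk(x, y, bx2, by2, ax2, ay2)
            yield from walk(x + bx2, y + by2, ax, ay, bx - bx2, by - by2)
            yield from walk(
                x + (ax - dax) + (bx2 - dbx),
                y + (ay - day) + (by2 - dby),
                -bx2,
                -by2,
                -(ax - ax2),
                -(ay - ay2),
            )

    # the primary axis is fixed (axis 1 of the grid handed in) rather than
    # chosen by length, so that transposed grids give genuinely different
    # traversals on rectangles
    yield from walk(0, 0, 0, w, h, 0)


def hilbert_ordering(grid_shape, reflect=None, transpose=None) -> Ordering:
    """Generalized Hilbert traversal of the (reflected, transposed) grid.

    2D: generalized Hilbert curve over the whole rectangle.  3D: Hilbert
    curve within each trailing-2-axes slab, slabs visited boustrophedon
    along the leading axis (alternate slabs reversed), so consecutive
    sequence positions remain grid-adjacent everywhere.
    """
    cells, reflect, axes = _transformed_cells(grid_shape, reflect, transpose)
    shape = cells.shape
    if len(shape) == 2:
        path = list(_gilbert2d(shape[0], shape[1]))
        rows = np.array([p[0] for p in path])
        cols = np.array([p[1] for p in path])
        perm = cells[rows, cols]
    elif len(shape) == 3:
        path = list(_gilbert2d(shape[1], shape[2]))
        rows = np.array([p[0] for p in path])
        cols = np.array([p[1] for p in path])
        parts = []
        for i in range(shape[0]):
            slab = cells[i][rows, cols]
            parts.append(slab[::-1] if i % 2 else slab)
        perm = np.concatenate(parts)
    else:
        raise ValueError("hilbert ordering supports 2D and 3D grids")
    return Ordering(
        name="hilbert",
        grid_shape=tuple(grid_shape),
        perm=perm,
        descriptor={"class": "hilbert", "shape": list(grid_shape), "reflect": list(reflect), "transpose": list(axes)},
    )


def random_ordering(grid_shape, seed: int = 0) -> Ordering:
    """Uniformly random permutation of the grid, reproducible by seed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(int(np.prod(grid_shape)))
    return Ordering(
        name="random",
        grid_shape=tuple(grid_shape),
        perm=perm,
        descriptor={"class": "random", "shape": list(grid_shape), "seed": int(seed)},
    )


_CONSTRUCTORS = {
    "raster": raster_ordering,
    "s_curve": s_curve_ordering,
    "hilbert": hilbert_ordering,
}


def make_ordering(descriptor: dict) -> Ordering:
    """Rebuild an ordering from its serialized descriptor."""
    cls = descriptor["class"]
    shape = tuple(descriptor["shape"])
    if cls == "random":
        return random_ordering(shape, seed=int(descriptor.get("seed", 0)))
    if cls not in _CONSTRUCTORS:
        raise ValueError(f"unknown ordering class {cls!r}")
    return _CONSTRUCTORS[cls](
        shape,
        reflect=descriptor.get("reflect"),
        transpose=descriptor.get("transpose"),
    )


# 3D ensemble: identity plus the six single/double axis reflections
_REFLECT_3D = [
    (False, False, False),
    (True, False, False),
    (False, True, False),
    (False, False, True),
    (True, True, False),
    (True, False, True),
    (False, True, True),
]


def ensemble_orderings(
    ordering_class: str, grid_shape, count: int | None = None, seed: int = 0
) -> list[Ordering]:
    """The ensemble of `count` distinct orderings of one class.

    2D default: 8 = 4 reflection patterns x {no transpose, transpose};
    3D default: 7 = identity + single/double axis reflections.  The random
    class instead uses `count` distinct permutation seeds derived from
    `seed`.
    """
    grid_shape = tuple(grid_shape)
    nd = len(grid_shape)
    if nd not in (2, 3):
        raise ValueError("ensembles are defined for 2D and 3D grids")
    default = 8 if nd == 2 else 7
    count = default if count is None else int(count)
    if ordering_class == "random":
        return [random_ordering(grid_shape, seed=seed + i) for i in range(count)]
    if nd == 2:
        variants = [
            {"reflect": list(r), "transpose": [1, 0] if t else [0, 1]}
            for t in (False, True)
            for r in [(False, False), (True, False), (False, True), (True, True)]
        ]
    else:
        variants = [{"reflect": list(r), "transpose": [0, 1, 2]} for r in _REFLECT_3D]
    if count > len(variants):
        raise ValueError(f"at most {len(variants)} {nd}D orderings available, requested {count}")
    out = [
        make_ordering({"class": ordering_class, "shape": list(grid_shape), **v})
        for v in variants[:count]
    ]
    seen = {tuple(o.perm.tolist()) for o in out}
    if len(seen) != len(out):
        raise RuntimeError("ensemble contains duplicate orderings")
    return out
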