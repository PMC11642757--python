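"""Generative model of a chromosomally mosaic blastocyst and its biopsy.

The embryo is abstracted as 256 cells (8 synchronous division rounds from the
zygote) carrying a binary ploidy label.  A meiotic error makes every cell
aneuploid; mitotic errors found aneuploid clones during cleavage.  Cells are
arranged on a sphere (a trophectoderm-like shell); aneuploid cells are placed
with a tunable degree of spatial clustering ("dispersal"), and a biopsy of
five spatially adjacent cells is classified as euploid, mosaic or aneuploid —
mimicking clinical PGT-A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal

import numpy as np

from ._kernels import grow_clusters, biopsy_counts_batch

__all__ = [
    "ErrorRates",
    "ModelConfig",
    "EmbryoGeometry",
    "LineageOutcome",
    "Embryo",
    "Biopsy",
    "BiopsyClass",
    "SummaryStats",
    "make_geometry",
    "simulate_lineage",
    "simulate_lineages",
    "place_aneuploid",
    "take_biopsy",
    "classify_biopsy",
    "classify_counts",
    "simulate_biopsy_proportions",
    "simulate_biopsy_counts",
]

CLASS_NAMES = ("euploid", "mosaic", "aneuploid")


@dataclass(frozen=True)
class ErrorRates:
    """Per-meiosis and per-mitosis error probabilities.

    The prior during inference is uniform on (0, 1) for both rates; the
    boundary values 0 and 1 are accepted so that degenerate lineages can be
    exercised directly.
    """

    meiotic: float
    mitotic: float

    def __post_init__(self) -> None:
        for name in ("meiotic", "mitotic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} error rate must lie in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.meiotic, self.mitotic], dtype=float)


@dataclass(frozen=True)
class ModelConfig:
    """Structural parameters of the embryo/biopsy simulator.

    n_rounds
        Number of synchronous division rounds from the zygote (default 8,
        giving a 256-cell blastocyst-stage embryo).
    biopsy_size
        Number of spatially adjacent cells removed per biopsy (default 5).
    dispersal
        Spatial clustering of aneuploid cells in [0, 1]: 0 = one contiguous
        patch, 1 = maximum spatial separation (uniform random placement).
    classification_rule
        ``threshold_20_70`` (default): <20% aneuploid cells -> euploid,
        20-70% -> mosaic, >70% -> aneuploid.  ``any_but_not_all``: mosaic iff
        some but not all biopsied cells are aneuploid.
    mitotic_convention
        ``per_daughter`` (default): each daughter of a euploid division
        independently becomes aneuploid with the mitotic rate.
        ``per_division_both_daughters``: the division itself errs with the
        mitotic rate, making both daughters aneuploid.  Both conventions share
        the per-cell marginal euploid probability (1-p)^n_rounds and differ
        only in clone-size correlation.
    """

    n_rounds: int = 8
    n_cells: int = 256
    biopsy_size: int = 5
    dispersal: float = 1.0
    classification_rule: Literal["threshold_20_70", "any_but_not_all"] = "threshold_20_70"
    mitotic_convention: Literal["per_daughter", "per_division_both_daughters"] = "per_daughter"

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.n_cells != 2**self.n_rounds:
            raise ValueError(f"n_cells must equal 2**n_rounds = {2**self.n_rounds}")
        if not (1 <= self.biopsy_size <= self.n_cells):
            raise ValueError("biopsy_size must lie in [1, n_cells]")
        if not (0.0 <= self.dispersal <= 1.0):
            raise ValueError("dispersal must lie in [0, 1]")
        if self.classification_rule not in ("threshold_20_70", "any_but_not_all"):
            raise ValueError(f"unknown classification_rule {self.classification_rule!r}")
        if self.mitotic_convention not in ("per_daughter", "per_division_both_daughters"):
            raise ValueError(f"unknown mitotic_convention {self.mitotic_convention!r}")

    def with_dispersal(self, dispersal: float) -> "ModelConfig":
        return replace(self, dispersal=float(dispersal))


@dataclass(frozen=True)
class EmbryoGeometry:
    """Deterministic spatial arrangement of the n_cells cells.

    positions
        (n_cells, 3) unit vectors from a Fibonacci lattice on the sphere.
    neighbor_order
        (n_cells, n_cells - 1) matrix: row i lists every other cell id in
        increasing chordal distance from cell i, ties broken by cell index.
    """

    positions: np.ndarray = field(repr=False)
    neighbor_order: np.ndarray = field(repr=False)
    default_index_cell: int = 0

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def biopsy_cells(self, index_cell: int, biopsy_size: int) -> np.ndarray:
        """Cell ids of the biopsy anchored at ``index_cell``: the index cell
        plus its ``biopsy_size - 1`` nearest neighbors."""
        if not (0 <= index_cell < self.n_cells):
            raise ValueError(f"index_cell {index_cell} out of range")
        return np.concatenate(
            ([index_cell], self.neighbor_order[index_cell, : biopsy_size - 1])
        )


@dataclass(frozen=True)
class LineageOutcome:
    is_meiotic: bool
    n_aneuploid: int


@dataclass(frozen=True)
class Embryo:
    geometry: EmbryoGeometry
    ploidy: np.ndarray  # bool per cell; True = aneuploid
    n_aneuploid: int
    dispersal: float


@dataclass(frozen=True)
class Biopsy:
    cell_ids: np.ndarray
    aneuploid_count: int

    @property
    def size(self) -> int:
        return len(self.cell_ids)


# string enum kept lightweight; integer codes 0/1/2 are used internally
BiopsyClass = Literal["euploid", "mosaic", "aneuploid"]


@dataclass(frozen=True)
class SummaryStats:
    """The ABC summary statistic: biopsy-class proportions (a simplex)."""

    prop_euploid: float
    prop_mosaic: float
    prop_aneuploid: float

    def as_array(self) -> np.ndarray:
        return np.array([self.prop_euploid, self.prop_mosaic, self.prop_aneuploid])

    @classmethod
    def from_classes(cls, classes: np.ndarray) -> "SummaryStats":
        counts = np.bincount(classes, minlength=3)
        props = counts / counts.sum()
        return cls(*props.tolist())


@lru_cache(maxsize=8)
def make_geometry(n_cells: int) -> EmbryoGeometry:
    """Place ``n_cells`` cells on the unit sphere with a Fibonacci lattice.

    The lattice is deterministic and near-uniform; neighbor orderings are by
    chordal (Euclidean) distance with ties broken by the lower cell index.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    i = np.arange(n_cells)
    z = 1.0 - (2.0 * i + 1.0) / n_cells
    golden_angle = math.pi * (3.0 - math.sqrt(5.0))
    theta = golden_angle * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # stable argsort on the distance matrix breaks exact ties by index
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")[:, 1:]  # drop self (distance 0)
    return EmbryoGeometry(
        positions=positions,
        neighbor_order=np.ascontiguousarray(order.astype(np.int64)),
        default_index_cell=0,
    )


def simulate_lineages(
    theta: ErrorRates, config: ModelConfig, n_embryos: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised lineage simulation: aneuploid cell count for each embryo.

    With probability ``meiotic`` the embryo is fully aneuploid.  Otherwise the
    euploid cell count E starts at 1 and is propagated through ``n_rounds``
    synchronous divisions; aneuploid cells breed true.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    n_cells = config.n_cells
    n_an = np.full(n_embryos, n_cells, dtype=np.int64)
    mitotic_only = rng.random(n_embryos) >= theta.meiotic
    k = int(mitotic_only.sum())
    if k:
        e = np.ones(k, dtype=np.int64)
        p = theta.mitotic
        if config.mitotic_convention == "per_daughter":
            for _ in range(config.n_rounds):
                e = rng.binomial(2 * e, 1.0 - p)
        else:  # per_division_both_daughters
            for _ in range(config.n_rounds):
                e = 2 * rng.binomial(e, 1.0 - p)
        n_an[mitotic_only] = n_cells - e
    return n_an


def simulate_lineage(
    theta: ErrorRates, config: ModelConfig, rng: np.random.Generator
) -> LineageOutcome:
    """Single-embryo lineage draw (see :func:`simulate_lineages`)."""
    if rng.random() < theta.meiotic:
        return LineageOutcome(is_meiotic=True, n_aneuploid=config.n_cells)
    e = 1
    p = theta.mitotic
    if config.mitotic_convention == "per_daughter":
        for _ in range(config.n_rounds):
            e = int(rng.binomial(2 * e, 1.0 - p))
    else:
        for _ in range(config.n_rounds):
            e = 2 * int(rng.binomial(e, 1.0 - p))
    return LineageOutcome(is_meiotic=False, n_aneuploid=config.n_cells - e)


def n_cluster_seeds(n_aneuploid: int, dispersal: float) -> int:
    """Number of cluster seeds: max(1, round(dispersal * n_aneuploid)),
    half-away-from-zero rounding, clamped to n_aneuploid."""
    s = max(1, int(math.floor(dispersal * n_aneuploid + 0.5)))
    return min(s, n_aneuploid)


def place_aneuploid(
    geometry: EmbryoGeometry,
    n_aneuploid: int,
    dispersal: float,
    rng: np.random.Generator,
) -> Embryo:
    """Assign aneuploid labels with seed-and-grow spatial clustering.

    ``s = max(1, round(dispersal * n_aneuploid))`` seed cells are chosen
    uniformly without replacement; clusters then grow by repeatedly picking a
    cluster uniformly at random and marking the nearest not-yet-marked cell in
    its seed's neighbor ordering.  dispersal 0 yields a single contiguous
    patch; dispersal 1 marks every aneuploid cell as its own seed (a uniform
    random subset).
    """
    n_cells = geometry.n_cells
    if not (0 <= n_aneuploid <= n_cells):
        raise ValueError(f"n_aneuploid must lie in [0, {n_cells}]")
    if not (0.0 <= dispersal <= 1.0):
        raise ValueError("dispersal must lie in [0, 1]")
    ploidy = np.zeros(n_cells, dtype=bool)
    if n_aneuploid == 0:
        return Embryo(geometry, ploidy, 0, dispersal)
    if n_aneuploid == n_cells:
        ploidy[:] = True
        return Embryo(geometry, ploidy, n_cells, dispersal)
    s = n_cluster_seeds(n_aneuploid, dispersal)
    seeds = rng.choice(n_cells, size=s, replace=False)
    cluster_choices = rng.integers(0, s, size=n_aneuploid - s)
    marked = grow_clusters(
        geometry.neighbor_order, seeds.astype(np.int64), cluster_choices.astype(np.int64)
    )
    ploidy[marked] = True
    return Embryo(geometry, ploidy, n_aneuploid, dispersal)


def take_biopsy(embryo: Embryo, index_cell: int | None = None, biopsy_size: int = 5) -> Biopsy:
    """Remove the index cell plus its ``biopsy_size - 1`` nearest neighbors."""
    geom = embryo.geometry
    if index_cell is None:
        index_cell = geom.default_index_cell
    cells = geom.biopsy_cells(index_cell, biopsy_size)
    return Biopsy(cell_ids=cells, aneuploid_count=int(embryo.ploidy[cells].sum()))


def classify_counts(
    counts: np.ndarray, biopsy_size: int, rule: str = "threshold_20_70"
) -> np.ndarray:
    """Vectorised biopsy classification to integer codes 0/1/2
    (euploid/mosaic/aneuploid).

    Thresholds are applied to the aneuploid-cell proportion with exact
    integer arithmetic: <20% euploid, 20-70% mosaic (inclusive), >70%
    aneuploid.
    """
    counts = np.asarray(counts)
    if rule == "threshold_20_70":
        # c/size < 0.2  <=>  10c < 2*size ; c/size <= 0.7 <=> 10c <= 7*size
        cls = np.where(
            10 * counts < 2 * biopsy_size, 0, np.where(10 * counts <= 7 * biopsy_size, 1, 2)
        )
    elif rule == "any_but_not_all":
        cls = np.where(counts == 0, 0, np.where(counts == biopsy_size, 2, 1))
    else:
        raise ValueError(f"unknown classification rule {rule!r}")
    return cls.astype(np.int64)


def classify_biopsy(biopsy: Biopsy, rule: str = "threshold_20_70") -> str:
    return CLASS_NAMES[int(classify_counts(np.array([biopsy.aneuploid_count]), biopsy.size, rule)[0])]


def simulate_biopsy_counts(
    n_aneuploid: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
    geometry: EmbryoGeometry | None = None,
    index_cells: np.ndarray | None = None,
    second_index_cells: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Aneuploid cell counts of one (optionally two) biopsies per embryo.

    Runs spatial placement for every mosaic embryo and tallies the biopsy
    overlap; fully euploid/aneuploid embryos are resolved without placement.
    Returns ``(counts1, counts2)`` with ``counts2`` None when no second
    biopsy index is supplied.
    """
    if geometry is None:
        geometry = make_geometry(config.n_cells)
    n = len(n_aneuploid)
    if index_cells is None:
        index_cells = np.full(n, geometry.default_index_cell, dtype=np.int64)
    idx2 = second_index_cells if second_index_cells is not None else np.full(n, -1, dtype=np.int64)
    # biopsy cell sets for all possible index cells
    bsets = np.empty((config.n_cells, config.biopsy_size), dtype=np.int64)
    for i in range(config.n_cells):
        bsets[i] = geometry.biopsy_cells(i, config.biopsy_size)
    n_an = np.asarray(n_aneuploid, dtype=np.int64)
    index_cells = np.asarray(index_cells, dtype=np.int64)
    idx2 = np.asarray(idx2, dtype=np.int64)

    # homogeneous embryos need no placement
    c1 = np.where(n_an == config.n_cells, config.biopsy_size, 0).astype(np.int64)
    c2 = c1.copy()
    mosaic = np.flatnonzero((n_an > 0) & (n_an < config.n_cells))
    # chunked so the uniform-variate buffer stays modest at large batch sizes
    chunk = 65536
    for lo in range(0, len(mosaic), chunk):
        sel = mosaic[lo : lo + chunk]
        seed_counts = np.array(
            [n_cluster_seeds(int(a), config.dispersal) for a in n_an[sel]], dtype=np.int64
        )
        u = rng.random((len(sel), config.n_cells))
        a, b = biopsy_counts_batch(
            geometry.neighbor_order, bsets, n_an[sel], seed_counts,
            index_cells[sel], idx2[sel], u,
        )
        c1[sel] = a
        c2[sel] = b
    return c1, (c2 if second_index_cells is not None else None)


def simulate_biopsy_proportions(
    theta: ErrorRates,
    config: ModelConfig,
    n_embryos: int,
    rng: np.random.Generator,
    geometry: EmbryoGeometry | None = None,
) -> SummaryStats:
    """End-to-end trial: lineage -> placement -> one biopsy at the default
    index cell -> classification; returns biopsy-class proportions."""
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    n_an = simulate_lineages(theta, config, n_embryos, rng)
    counts, _ = simulate_biopsy_counts(n_an, config, rng, geometry=geometry)
    classes = classify_counts(counts, config.biopsy_size, config.classification_rule)
    return SummaryStats.from_classes(classes)
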