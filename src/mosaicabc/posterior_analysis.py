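"""Posterior predictive characterization of whole embryos.

Where the ABC stage sees only biopsy-class proportions, this module asks what
the *embryos* behind a fitted posterior look like: the split into fully
euploid / mosaic / fully aneuploid embryos, the distribution of aneuploid
cell fractions, how biopsy classes map onto embryo types, and how often a
second biopsy of the same embryo agrees with the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abc_engine import PosteriorSample
from .embryo_model import (
    CLASS_NAMES,
    ErrorRates,
    ModelConfig,
    make_geometry,
    classify_counts,
    simulate_biopsy_counts,
    simulate_lineages,
)

__all__ = [
    "EMBRYO_TYPE_NAMES",
    "PredictiveConfig",
    "PredictiveTables",
    "classify_embryo",
    "classify_embryos",
    "draw_predictive_embryos",
    "tabulate_predictive",
]

EMBRYO_TYPE_NAMES = ("fully_euploid", "mosaic", "fully_aneuploid")


@dataclass(frozen=True)
class PredictiveConfig:
    """Posterior predictive sample sizes.

    Defaults mirror the full-scale analysis: 1,000 parameter draws from the
    posterior, 1,000 embryos per draw (10^6 embryos per dispersal level).
    The second biopsy is anchored at a uniformly drawn index cell and may
    overlap the first (no cell removal is modelled); set ``overlap_allowed``
    False to restrict the second index cell to positions whose biopsy shares
    no cell with the first.
    """

    n_posterior_draws: int = 1000
    n_embryos_per_draw: int = 1000
    overlap_allowed: bool = True
    histogram_bins: int = 20

    def __post_init__(self) -> None:
        if self.n_posterior_draws < 1 or self.n_embryos_per_draw < 1:
            raise ValueError("draw counts must be >= 1")


def classify_embryos(n_aneuploid: np.ndarray, n_cells: int) -> np.ndarray:
    """Embryo type codes: 0 fully euploid, 1 mosaic (any but not all cells
    aneuploid), 2 fully aneuploid."""
    n_an = np.asarray(n_aneuploid)
    if np.any((n_an < 0) | (n_an > n_cells)):
        raise ValueError(f"n_aneuploid must lie in [0, {n_cells}]")
    return np.where(n_an == 0, 0, np.where(n_an == n_cells, 2, 1)).astype(np.int64)


def classify_embryo(n_aneuploid: int, n_cells: int) -> str:
    return EMBRYO_TYPE_NAMES[int(classify_embryos(np.array([n_aneuploid]), n_cells)[0])]


def draw_predictive_embryos(
    posterior: PosteriorSample,
    model_config: ModelConfig | None = None,
    pred_config: PredictiveConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate embryos under parameter pairs drawn from the posterior.

    Draws ``n_posterior_draws`` (meiotic, mitotic) pairs weighted with
    replacement and simulates ``n_embryos_per_draw`` embryo lineages per
    pair.  Returns one record per embryo with columns ``meiotic``,
    ``mitotic``, ``n_aneuploid`` and ``embryo_type``.
    """
    model_config = model_config or ModelConfig()
    pred_config = pred_config or PredictiveConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if posterior.thetas.shape[0] == 0:
        raise ValueError("empty posterior")
    w = posterior.weights / posterior.weights.sum()
    draw_idx = rng.choice(len(w), size=pred_config.n_posterior_draws, replace=True, p=w)
    n_per = pred_config.n_embryos_per_draw
    total = pred_config.n_posterior_draws * n_per
    meiotic = np.repeat(posterior.thetas[draw_idx, 0], n_per)
    mitotic = np.repeat(posterior.thetas[draw_idx, 1], n_per)
    n_an = np.empty(total, dtype=np.int64)
    for k, i in enumerate(draw_idx):
        theta = ErrorRates(float(posterior.thetas[i, 0]), float(posterior.thetas[i, 1]))
        n_an[k * n_per : (k + 1) * n_per] = simulate_lineages(theta, model_config, n_per, rng)
    return pd.DataFrame(
        {
            "meiotic": meiotic,
            "mitotic": mitotic,
            "n_aneuploid": n_an,
            "embryo_type": classify_embryos(n_an, model_config.n_cells),
        }
    )


@dataclass
class PredictiveTables:
    """Cross-tabulations of a posterior predictive embryo sample."""

    embryo_type_proportions: pd.Series
    aneuploid_fraction_counts: np.ndarray = field(repr=False)  # exact per-count bins
    aneuploid_fraction_histogram: pd.DataFrame = field(repr=False)  # coarse bins
    biopsy_by_embryo: pd.DataFrame  # first-biopsy class x embryo type, counts
    rebiopsy: pd.DataFrame  # first-biopsy class x second-biopsy class, counts
    concordance: pd.Series  # per first-biopsy class: P(second class == first)
    n_embryos: int
    provenance: dict = field(default_factory=dict)

    def share_aneuploid_biopsies_from_mosaic(self) -> float:
        """Among first biopsies classified aneuploid, the fraction whose
        source embryo is mosaic."""
        row = self.biopsy_by_embryo.loc["aneuploid"]
        return float(row["mosaic"] / row.sum())

    def rebiopsy_long_format(self) -> pd.DataFrame:
        """Ribbon-plot-ready long table: first class, second class, count."""
        long = self.rebiopsy.stack().rename("count").reset_index()
        long.columns = ["first_class", "second_class", "count"]
        return long


def tabulate_predictive(
    records: pd.DataFrame,
    model_config: ModelConfig | None = None,
    rng: np.random.Generator | None = None,
    pred_config: PredictiveConfig | None = None,
) -> PredictiveTables:
    """Biopsy both ways and cross-tabulate the predictive sample.

    The first biopsy is anchored at the geometry's default index cell, the
    second at a uniformly drawn index cell; both are classified with the
    20%/70% thresholds.
    """
    model_config = model_config or ModelConfig()
    pred_config = pred_config or PredictiveConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if len(records) == 0:
        raise ValueError("empty predictive sample")
    n_cells = model_config.n_cells
    geometry = make_geometry(n_cells)
    n = len(records)
    n_an = records["n_aneuploid"].to_numpy()

    if pred_config.overlap_allowed:
        candidates = np.arange(n_cells)
    else:
        first_set = set(geometry.biopsy_cells(geometry.default_index_cell, model_config.biopsy_size))
        candidates = np.array(
            [
                i
                for i in range(n_cells)
                if not first_set & set(geometry.biopsy_cells(i, model_config.biopsy_size))
            ]
        )
    idx2 = candidates[rng.integers(0, len(candidates), size=n)]
    c1, c2 = simulate_biopsy_counts(
        n_an, model_config, rng, geometry=geometry, second_index_cells=idx2
    )
    cls1 = classify_counts(c1, model_config.biopsy_size, "threshold_20_70")
    cls2 = classify_counts(c2, model_config.biopsy_size, "threshold_20_70")
    etype = records["embryo_type"].to_numpy()

    type_counts = np.bincount(etype, minlength=3)
    embryo_type_proportions = pd.Series(
        type_counts / n, index=list(EMBRYO_TYPE_NAMES), name="proportion"
    )

    frac_counts = np.bincount(n_an, minlength=n_cells + 1)
    edges = np.linspace(0.0, 1.0, pred_config.histogram_bins + 1)
    hist, _ = np.histogram(n_an / n_cells, bins=edges)
    histogram = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": hist}
    )

    def crosstab(a, b, rows, cols):
        m = np.zeros((3, 3), dtype=np.int64)
        np.add.at(m, (a, b), 1)
        return pd.DataFrame(m, index=list(rows), columns=list(cols))

    biopsy_by_embryo = crosstab(cls1, etype, CLASS_NAMES, EMBRYO_TYPE_NAMES)
    rebiopsy = crosstab(cls1, cls2, CLASS_NAMES, CLASS_NAMES)
    row_sums = rebiopsy.sum(axis=1)
    concordance = pd.Series(
        np.where(row_sums > 0, np.diag(rebiopsy) / row_sums.replace(0, 1), np.nan),
        index=list(CLASS_NAMES),
        name="concordance",
    )

    return PredictiveTables(
        embryo_type_proportions=embryo_type_proportions,
        aneuploid_fraction_counts=frac_counts,
        aneuploid_fraction_histogram=histogram,
        biopsy_by_embryo=biopsy_by_embryo,
        rebiopsy=rebiopsy,
        concordance=concordance,
        n_embryos=n,
        provenance={
            "dispersal": model_config.dispersal,
            "n_embryos": n,
            "overlap_allowed": pred_config.overlap_allowed,
        },
    )
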