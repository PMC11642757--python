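"""Adaptive population Monte Carlo ABC for (meiotic, mitotic) error rates.

The likelihood of the biopsy-class proportions under the embryo model is
intractable, but simulation is cheap, so inference proceeds by approximate
Bayesian computation with an adaptively tightened tolerance schedule: an
initial prior sample is culled to its best-matching half, and each iteration
replenishes the population with kernel-perturbed proposals weighted by an
importance ratio, stopping once newly proposed particles almost never improve
on the previous tolerance.

The summary statistic is the simplex of euploid/mosaic/aneuploid biopsy
proportions and the discrepancy is the Euclidean distance between simplices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .embryo_model import (
    ErrorRates,
    ModelConfig,
    SummaryStats,
    classify_counts,
    make_geometry,
    simulate_biopsy_counts,
    simulate_lineages,
)

__all__ = [
    "TargetProportions",
    "ABCConfig",
    "PosteriorSample",
    "ClassProbabilityLookup",
    "distance",
    "run_abc",
    "posterior_summary",
    "make_embryo_simulator",
    "weighted_mean",
    "weighted_quantile",
    "weighted_corr",
]

PARAM_NAMES = ("meiotic", "mitotic")


@dataclass(frozen=True)
class TargetProportions:
    """Observed (or synthetic) biopsy-class proportions used as ABC target."""

    label: str
    prop_euploid: float
    prop_mosaic: float
    prop_aneuploid: float
    n_biopsies: int | None = None

    def __post_init__(self) -> None:
        v = self.as_array()
        if np.any(v < 0):
            raise ValueError("proportions must be nonnegative")
        total = float(v.sum())
        if abs(total - 1.0) > 0.005:
            raise ValueError(
                f"proportions of {self.label!r} sum to {total:.4f}, expected ~1"
            )
        if abs(total - 1.0) > 1e-9:  # renormalize printed/rounded triples
            v = v / total
            object.__setattr__(self, "prop_euploid", float(v[0]))
            object.__setattr__(self, "prop_mosaic", float(v[1]))
            object.__setattr__(self, "prop_aneuploid", float(v[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.prop_euploid, self.prop_mosaic, self.prop_aneuploid])


@dataclass(frozen=True)
class ABCConfig:
    """Settings of the adaptive PMC sampler.

    With the defaults (N = 2000 particles, keep fraction 0.5) the retained
    posterior sample holds 1000 particles.  ``p_acc_min`` is the stopping
    threshold on the fraction of fresh proposals that beat the previous
    tolerance.
    """

    n_particles: int = 2000
    keep_fraction: float = 0.5
    p_acc_min: float = 0.05
    n_embryos_per_trial: int = 1000
    max_iterations: int = 60
    lookup_placements_per_row: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 < self.keep_fraction < 1.0):
            raise ValueError("keep_fraction must lie in (0, 1)")
        if self.n_retained < 2:
            raise ValueError("retained set must hold at least 2 particles")
        if self.n_retained >= self.n_particles:
            raise ValueError("keep_fraction leaves no room for proposals")

    @property
    def n_retained(self) -> int:
        return math.ceil(self.keep_fraction * self.n_particles)


@dataclass
class PosteriorSample:
    """Weighted particle approximation of p(theta | target)."""

    thetas: np.ndarray  # (n_retained, 2)
    weights: np.ndarray  # normalized, sum to 1
    distances: np.ndarray
    tolerance_history: list[float]
    p_acc_history: list[float]
    n_iterations: int
    param_names: tuple[str, ...] = PARAM_NAMES
    meta: dict = field(default_factory=dict)

    def mean(self) -> np.ndarray:
        return weighted_mean(self.thetas, self.weights)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """Per-parameter equal-tailed weighted credible interval, (2, n_params)."""
        lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
        out = np.empty((2, self.thetas.shape[1]))
        for j in range(self.thetas.shape[1]):
            out[0, j] = weighted_quantile(self.thetas[:, j], self.weights, lo)
            out[1, j] = weighted_quantile(self.thetas[:, j], self.weights, hi)
        return out


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    return np.asarray(values, dtype=float).T @ (w / w.sum())


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray | float:
    """Weighted quantile by cumulative-weight interpolation (stable sort,
    so ties resolve to the lower index)."""
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(q, cum, v)


def weighted_corr(x: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Pearson correlation."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mx, my = float(w @ x), float(w @ y)
    cov = float(w @ ((x - mx) * (y - my)))
    sx = math.sqrt(float(w @ (x - mx) ** 2))
    sy = math.sqrt(float(w @ (y - my) ** 2))
    return cov / (sx * sy)


def distance(sim, target) -> float:
    """Euclidean distance between two summary vectors (raw proportions)."""
    a = sim.as_array() if hasattr(sim, "as_array") else np.asarray(sim, dtype=float)
    b = target.as_array() if hasattr(target, "as_array") else np.asarray(target, dtype=float)
    return float(np.linalg.norm(a - b))


class ClassProbabilityLookup:
    """Biopsy-class probabilities conditional on the aneuploid cell count.

    Because the class of the default-index biopsy depends on the embryo only
    through (n_aneuploid, dispersal, geometry), ABC trials can sample biopsy
    classes from a precomputed (n_cells + 1, 3) probability table instead of
    re-running spatial placement.  At dispersal 1 placement is a uniform
    random subset, so the table is filled exactly from the hypergeometric
    distribution; at other dispersals each row is estimated from Monte Carlo
    placements.
    """

    def __init__(self, table: np.ndarray, dispersal: float):
        self.table = table
        self.dispersal = dispersal
        self._cdf = np.cumsum(table, axis=1)

    @classmethod
    def build(
        cls,
        config: ModelConfig,
        rng: np.random.Generator | None = None,
        n_placements: int = 2000,
    ) -> "ClassProbabilityLookup":
        n_cells, bsize = config.n_cells, config.biopsy_size
        table = np.zeros((n_cells + 1, 3))
        table[0, 0] = 1.0
        table[n_cells, 2] = 1.0
        k = np.arange(bsize + 1)
        cls_of_count = classify_counts(k, bsize, config.classification_rule)
        if config.dispersal == 1.0:
            for n_an in range(1, n_cells):
                pmf = sps.hypergeom.pmf(k, n_cells, n_an, bsize)
                for c in range(3):
                    table[n_an, c] = pmf[cls_of_count == c].sum()
        else:
            if rng is None:
                raise ValueError("Monte Carlo lookup construction needs an rng")
            geometry = make_geometry(n_cells)
            for n_an in range(1, n_cells):
                arr = np.full(n_placements, n_an, dtype=np.int64)
                counts, _ = simulate_biopsy_counts(arr, config, rng, geometry=geometry)
                classes = classify_counts(counts, bsize, config.classification_rule)
                table[n_an] = np.bincount(classes, minlength=3) / n_placements
        return cls(table, config.dispersal)

    def sample_classes(self, n_aneuploid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        c = self._cdf[n_aneuploid]
        u = rng.random(len(n_aneuploid))
        return (u >= c[:, 0]).astype(np.int64) + (u >= c[:, 1])


def make_embryo_simulator(
    model_config: ModelConfig,
    n_embryos_per_trial: int,
    lookup: ClassProbabilityLookup | None = None,
    rng_lookup: np.random.Generator | None = None,
    lookup_placements: int = 2000,
) -> Callable[[np.ndarray, np.random.Generator], np.ndarray]:
    """Batch simulator mapping parameter pairs to biopsy-class proportions.

    Uses the class-probability lookup when provided (or builds one), falling
    back to the exact per-embryo placement pipeline otherwise.
    """
    if lookup is None:
        lookup = ClassProbabilityLookup.build(
            model_config, rng=rng_lookup, n_placements=lookup_placements
        )

    def simulator(thetas: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        out = np.empty((len(thetas), 3))
        for i, (m, p) in enumerate(thetas):
            n_an = simulate_lineages(
                ErrorRates(float(m), float(p)), model_config, n_embryos_per_trial, rng
            )
            classes = lookup.sample_classes(n_an, rng)
            out[i] = np.bincount(classes, minlength=3) / n_embryos_per_trial
        return out

    return simulator


def _kernel_mixture_weights(
    proposals: np.ndarray,
    retained: np.ndarray,
    retained_weights: np.ndarray,
    kernel_var: np.ndarray,
) -> np.ndarray:
    """Importance weights: uniform prior density over the weight-normalized
    Gaussian kernel mixture density at each proposal."""
    w = retained_weights / retained_weights.sum()
    diff = proposals[:, None, :] - retained[None, :, :]  # (n_prop, n_ret, d)
    log_norm = -0.5 * np.sum(np.log(2.0 * np.pi * kernel_var))
    expo = -0.5 * np.sum(diff**2 / kernel_var, axis=2) + log_norm
    mix = np.exp(expo) @ w
    with np.errstate(divide="ignore"):
        out = 1.0 / mix
    if not np.all(np.isfinite(out)):
        bad = np.flatnonzero(~np.isfinite(out))
        raise FloatingPointError(
            f"non-finite importance weight for {len(bad)} proposals "
            f"(first at {proposals[bad[0]]}, kernel_var={kernel_var})"
        )
    return out


def _sample_prior(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform(0,1)^dim, open at the boundaries."""
    x = rng.random((n, dim))
    while True:
        bad = x == 0.0
        if not bad.any():
            return x
        x[bad] = rng.random(int(bad.sum()))


def run_abc(
    target: TargetProportions | Sequence[float] | np.ndarray,
    model_config: ModelConfig | None = None,
    abc_config: ABCConfig | None = None,
    rng: np.random.Generator | None = None,
    simulator: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
    n_params: int = 2,
) -> PosteriorSample:
    """Adaptive population Monte Carlo ABC.

    1. Draw N particles from the uniform prior, simulate, keep the
       best-matching ceil(alpha * N) with unit weights; the largest retained
       distance is the first tolerance.
    2. Each iteration draws N - N_alpha proposals by weighted resampling of
       the retained set perturbed by a diagonal Gaussian kernel whose
       per-coordinate variance is twice the weighted empirical variance of
       the retained particles (proposals outside the open unit square are
       redrawn).  Proposal weights are prior density over the kernel-mixture
       density; the merged population is re-culled to N_alpha.
    3. Stop when the fraction of proposals beating the previous tolerance
       drops to ``p_acc_min`` or the iteration cap is reached.
    """
    model_config = model_config or ModelConfig()
    abc_config = abc_config or ABCConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if simulator is None:
        simulator = make_embryo_simulator(
            model_config,
            abc_config.n_embryos_per_trial,
            rng_lookup=rng,
            lookup_placements=abc_config.lookup_placements_per_row,
        )
    target_vec = (
        target.as_array() if hasattr(target, "as_array") else np.asarray(target, dtype=float)
    )

    n_total = abc_config.n_particles
    n_keep = abc_config.n_retained

    thetas = _sample_prior(n_total, n_params, rng)
    summaries = simulator(thetas, rng)
    dists = np.linalg.norm(summaries - target_vec, axis=1)
    order = np.argsort(dists, kind="stable")[:n_keep]
    thetas, dists = thetas[order], dists[order]
    weights = np.ones(n_keep)
    tolerance_history = [float(dists.max())]
    p_acc_history: list[float] = []

    it = 0
    while it < abc_config.max_iterations:
        it += 1
        wn = weights / weights.sum()
        mu = wn @ thetas
        kernel_var = 2.0 * (wn @ (thetas - mu) ** 2)
        kernel_var = np.maximum(kernel_var, 1e-20)

        n_new = n_total - n_keep
        proposals = np.empty((n_new, n_params))
        need = np.arange(n_new)
        while need.size:
            parents = rng.choice(n_keep, size=need.size, p=wn)
            cand = thetas[parents] + rng.normal(0.0, np.sqrt(kernel_var), (need.size, n_params))
            ok = np.all((cand > 0.0) & (cand < 1.0), axis=1)
            proposals[need[ok]] = cand[ok]
            need = need[~ok]

        new_w = _kernel_mixture_weights(proposals, thetas, weights, kernel_var)
        new_summaries = simulator(proposals, rng)
        new_dists = np.linalg.norm(new_summaries - target_vec, axis=1)
        p_acc = float(np.mean(new_dists < tolerance_history[-1]))

        all_thetas = np.vstack([thetas, proposals])
        all_dists = np.concatenate([dists, new_dists])
        all_weights = np.concatenate([weights, new_w])
        order = np.argsort(all_dists, kind="stable")[:n_keep]
        thetas, dists, weights = all_thetas[order], all_dists[order], all_weights[order]

        tolerance_history.append(float(dists.max()))
        p_acc_history.append(p_acc)
        if p_acc <= abc_config.p_acc_min:
            break

    return PosteriorSample(
        thetas=thetas,
        weights=weights / weights.sum(),
        distances=dists,
        tolerance_history=tolerance_history,
        p_acc_history=p_acc_history,
        n_iterations=it,
        param_names=PARAM_NAMES[:n_params] if n_params <= 2 else tuple(f"p{i}" for i in range(n_params)),
        meta={
            "target": target_vec.tolist(),
            "dispersal": model_config.dispersal,
            "n_particles": n_total,
            "n_retained": n_keep,
            "n_embryos_per_trial": abc_config.n_embryos_per_trial,
        },
    )


def posterior_summary(posterior: PosteriorSample, level: float = 0.95):
    """Weighted mean and equal-tailed credible interval per parameter."""
    import pandas as pd

    if posterior.thetas.size == 0:
        raise ValueError("empty posterior")
    mean = posterior.mean()
    ci = posterior.credible_interval(level)
    return pd.DataFrame(
        {"mean": mean, "ci_low": ci[0], "ci_high": ci[1]},
        index=list(posterior.param_names),
    )
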