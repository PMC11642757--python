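"""Published PGT-A biopsy-class proportions and synthetic target generation.

The study catalog freezes the class proportions printed in four clinical
PGT-A reports; they are the only observed data the inference consumes.  The
synthetic generator produces targets from *known* error rates so that
parameter recovery can be tested end to end without any external data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .abc_engine import TargetProportions
from .embryo_model import ErrorRates, ModelConfig, simulate_biopsy_proportions

__all__ = [
    "StudyCatalog",
    "SyntheticTargetSpec",
    "published_targets",
    "catalog_checksum",
    "generate_synthetic_target",
]

StudyCatalog = dict[str, TargetProportions]

# Frozen published proportions (euploid, mosaic, aneuploid).  "capalbo" uses
# the precise values reported for the 6,766-biopsy clinical sample; a rounded
# two-digit variant of the same study is kept alongside because downstream
# summary tables print at that precision.
_CATALOG_VALUES: tuple[tuple[str, float, float, float, int | None], ...] = (
    ("capalbo", 0.232, 0.187, 0.581, 6766),
    ("capalbo_rounded", 0.23, 0.19, 0.58, 6766),
    ("clarke", 0.49, 0.18, 0.33, None),
    ("munne", 0.53, 0.15, 0.32, None),
    ("rodrigo", 0.51, 0.06, 0.43, None),
)


def published_targets() -> StudyCatalog:
    """The catalog of published biopsy-class proportions, keyed by study."""
    return {
        name: TargetProportions(name, e, m, a, n) for name, e, m, a, n in _CATALOG_VALUES
    }


def catalog_checksum() -> str:
    """SHA-256 over the canonical serialization of the catalog constants."""
    canonical = ";".join(
        f"{name}:{e!r},{m!r},{a!r},{n!r}" for name, e, m, a, n in _CATALOG_VALUES
    )
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """Recipe for a synthetic ABC target with known ground truth.

    ``n_biopsies`` is the number of simulated biopsies contributing
    multinomial sampling noise; ``None`` requests the (near) noise-free
    limit, computed from 10^5 simulated biopsies.
    """

    theta_true: ErrorRates
    dispersal: float = 1.0
    n_biopsies: int | None = None

    NOISE_FREE_N = 100_000

    def __post_init__(self) -> None:
        if self.n_biopsies is not None and self.n_biopsies < 1:
            raise ValueError("n_biopsies must be >= 1 when finite")
        if not (0.0 <= self.dispersal <= 1.0):
            raise ValueError("dispersal must lie in [0, 1]")


def generate_synthetic_target(
    spec: SyntheticTargetSpec,
    model_config: ModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TargetProportions:
    """Simulate biopsies at the true error rates and return their class
    proportions in the same form as the published targets."""
    model_config = (model_config or ModelConfig()).with_dispersal(spec.dispersal)
    rng = rng if rng is not None else np.random.default_rng()
    n = spec.n_biopsies if spec.n_biopsies is not None else spec.NOISE_FREE_N
    stats = simulate_biopsy_proportions(spec.theta_true, model_config, n, rng)
    label = (
        f"synthetic_m{spec.theta_true.meiotic:g}_p{spec.theta_true.mitotic:g}"
        f"_d{spec.dispersal:g}"
    )
    return TargetProportions(
        label=label,
        prop_euploid=stats.prop_euploid,
        prop_mosaic=stats.prop_mosaic,
        prop_aneuploid=stats.prop_aneuploid,
        n_biopsies=spec.n_biopsies,
    )
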