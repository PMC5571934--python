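"""Seeded synthetic cohorts of valve parameter sets.

Samples leaflet heights and widths within the published population
ranges to stand in for patient measurements in tests and demos.  The
published table gives central values with ranges but no distribution,
so sampling defaults to uniform over each [min, max]; a triangular
option peaks at the central value.  Dimensions are drawn independently
(no covariance structure is published), and the annulus is kept at its
nominal values unless an explicit jitter fraction is requested — both
simplifications that real cohorts would not share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurement import REFERENCE_RANGES
from .valve_model import (
    AnnulusGeometry,
    InfeasibleGeometryError,
    InvalidParameterError,
    LeafletDimensions,
    ValveParameters,
    DEFAULT_JUNCTION_PHASE,
)

__all__ = ["CohortSpec", "sample_parameters", "cohort_frame"]

_MAX_RESAMPLE = 1000

# (region, field kind) -> ValveParameters dims field
_FIELD_MAP = {
    ("anterior", "height"): "h_ant",
    ("P1", "height"): "h_p1",
    ("P2", "height"): "h_p2",
    ("P3", "height"): "h_p3",
    ("anterior", "width"): "w_ant",
    ("P1", "width"): "w_p1",
    ("P2", "width"): "w_p2",
    ("P3", "width"): "w_p3",
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    ``distribution`` is ``"uniform"`` over each published [min, max]
    or ``"triangular"`` peaked at the published central value.
    ``annulus_jitter`` (fraction, e.g. 0.1 for +-10%) perturbs the
    annulus dimensions uniformly around their nominal values; the
    default 0 keeps the annulus fixed, since no population range is
    published for it.
    """

    n: int = 1
    seed: int = 0
    distribution: str = "uniform"
    annulus_jitter: float = 0.0
    ranges: dict = field(default_factory=lambda: REFERENCE_RANGES)
    phi: float = DEFAULT_JUNCTION_PHASE

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidParameterError(f"cohort size must be >= 1, got {self.n}")
        if self.distribution not in ("uniform", "triangular"):
            raise InvalidParameterError(
                f"distribution must be 'uniform' or 'triangular', got {self.distribution!r}"
            )
        if not 0.0 <= self.annulus_jitter < 1.0:
            raise InvalidParameterError(
                f"annulus_jitter must lie in [0, 1), got {self.annulus_jitter}"
            )


def _draw(rng: np.random.Generator, dist: str, central: float, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    if dist == "uniform":
        return float(rng.uniform(lo, hi))
    mode = min(max(central, lo), hi)
    return float(rng.triangular(lo, mode, hi))


def sample_parameters(spec: CohortSpec) -> list[ValveParameters]:
    """Draw ``spec.n`` feasible valve parameter sets (deterministic per seed).

    Every height and width lies within its published range; draws whose
    junction offset would be infeasible (delta >= 1) are rejected and
    resampled, up to a bounded number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    nominal = AnnulusGeometry()
    out: list[ValveParameters] = []
    attempts = 0
    while len(out) < spec.n:
        if attempts >= _MAX_RESAMPLE + spec.n:
            raise InfeasibleGeometryError(
                f"could not draw {spec.n} feasible parameter sets within "
                f"{_MAX_RESAMPLE} resamples; ranges may force delta >= 1"
            )
        attempts += 1
        dims_kwargs = {}
        for (region, kind), fname in _FIELD_MAP.items():
            central, lo, hi = spec.ranges[region][kind]
            dims_kwargs[fname] = _draw(rng, spec.distribution, central, lo, hi)
        if spec.annulus_jitter > 0.0:
            j = spec.annulus_jitter
            annulus = AnnulusGeometry(
                ic=nominal.ic * float(rng.uniform(1 - j, 1 + j)),
                sl_ant=nominal.sl_ant * float(rng.uniform(1 - j, 1 + j)),
                sl_post=nominal.sl_post * float(rng.uniform(1 - j, 1 + j)),
            )
        else:
            annulus = nominal
        params = ValveParameters(annulus=annulus, dims=LeafletDimensions(**dims_kwargs), phi=spec.phi)
        try:
            params.partition  # feasibility: raises if delta >= 1
        except InfeasibleGeometryError:
            continue
        out.append(params)
    return out


def cohort_frame(cohort: list[ValveParameters]) -> pd.DataFrame:
    """Tabulate a cohort, one parameter set per row."""
    rows = []
    for i, p in enumerate(cohort):
        d, a = p.dims, p.annulus
        rows.append(
            {
                "id": i,
                "ic": a.ic,
                "sl_ant": a.sl_ant,
                "sl_post": a.sl_post,
                "h_ant": d.h_ant,
                "h_p1": d.h_p1,
                "h_p2": d.h_p2,
                "h_p3": d.h_p3,
                "w_ant": d.w_ant,
                "w_p1": d.w_p1,
                "w_p2": d.w_p2,
                "w_p3": d.w_p3,
                "phi": p.phi,
            }
        )
    return pd.DataFrame(rows)
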