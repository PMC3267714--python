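"""One-way (tornado) and probabilistic sensitivity analysis.

The tornado analysis evaluates the outcome with each parameter at its low
and high bound, all others held at base, ranked by outcome swing.  The
probabilistic analysis draws every sampled parameter independently from its
sampling distribution (default: uniform on [low, high], the only published
uncertainty information) and reports the mean and the 2.5th/97.5th
percentiles of the simulated outcome; 1000 draws is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .params import Parameter, ParameterRegistry, ValidationError

__all__ = [
    "TornadoResult",
    "PSAResult",
    "univariate_sensitivity",
    "probabilistic_sensitivity",
    "SAMPLERS",
]

OutcomeModel = Callable[[Mapping[str, float]], float]


@dataclass(frozen=True)
class TornadoResult:
    parameter: str
    outcome_at_low: float
    outcome_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


@dataclass(frozen=True)
class PSAResult:
    n_draws: int
    seed: int
    draws: np.ndarray
    mean: float
    percentile_2_5: float
    percentile_97_5: float


def univariate_sensitivity(
    model: OutcomeModel,
    registry: ParameterRegistry,
    parameters: Sequence[str] | None = None,
) -> list[TornadoResult]:
    """Tornado analysis: one result per sampled parameter, sorted by swing
    (largest first)."""
    base = registry.base_values()
    names = (list(parameters) if parameters is not None
             else [p.name for p in registry.sampled()])
    results = []
    for name in names:
        p = registry[name]
        out = {}
        for bound, value in (("low", p.low), ("high", p.high)):
            values = dict(base)
            values[name] = value
            try:
                out[bound] = model(values)
            except Exception as exc:
                raise RuntimeError(
                    f"outcome model failed for parameter {name!r} at {bound}") from exc
        results.append(TornadoResult(name, out["low"], out["high"]))
    return sorted(results, key=lambda r: r.swing, reverse=True)


def _sample_uniform(rng: np.random.Generator, p: Parameter, n: int) -> np.ndarray:
    return rng.uniform(p.low, p.high, size=n)


def _sample_triangular(rng: np.random.Generator, p: Parameter, n: int) -> np.ndarray:
    if p.low == p.high:
        return np.full(n, p.base)
    return rng.triangular(p.low, p.base, p.high, size=n)


SAMPLERS: dict[str, Callable[[np.random.Generator, Parameter, int], np.ndarray]] = {
    "uniform": _sample_uniform,
    "triangular": _sample_triangular,
}


def probabilistic_sensitivity(
    model: OutcomeModel,
    registry: ParameterRegistry,
    n_draws: int = 1000,
    seed: int = 0,
    distribution: str = "uniform",
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Identical seed implies identical draws; percentiles use linear
    interpolation between order statistics.  Parameters whose ranges are
    degenerate, derived or flagged inconsistent stay at base.
    """
    if n_draws < 2:
        raise ValidationError("n_draws must be at least 2")
    try:
        sampler = SAMPLERS[distribution]
    except KeyError:
        raise ValidationError(
            f"unknown sampling distribution {distribution!r}; "
            f"available: {sorted(SAMPLERS)}") from None
    sampled = registry.sampled()
    for p in sampled:
        if p.low > p.high:
            raise ValidationError(f"{p.name}: low {p.low} > high {p.high}")
    rng = np.random.default_rng(seed)
    base = registry.base_values()
    columns = {p.name: sampler(rng, p, n_draws) for p in sampled}
    draws = np.empty(n_draws)
    values = dict(base)
    for i in range(n_draws):
        for name, col in columns.items():
            values[name] = float(col[i])
        draws[i] = model(values)
    return PSAResult(
        n_draws=n_draws,
        seed=seed,
        draws=draws,
        mean=float(np.mean(draws)),
        percentile_2_5=float(np.percentile(draws, 2.5)),
        percentile_97_5=float(np.percentile(draws, 97.5)),
    )
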