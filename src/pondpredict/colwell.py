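"""Colwell-style predictability on month x state contingency tables.

Constancy, contingency and predictability are the information-theoretic
indices of Colwell (1974).  With column (month) sums X_j, row (state) sums
Y_i, grand total Z and cell counts N_ij:

    H(X)  = -sum_j (X_j/Z) log(X_j/Z)
    H(Y)  = -sum_i (Y_i/Z) log(Y_i/Z)
    H(XY) = -sum_ij (N_ij/Z) log(N_ij/Z)

    C = 1 - H(Y)/log s        (constancy)
    M = (H(X) + H(Y) - H(XY))/log s   (contingency)
    P = C + M = 1 - (H(XY) - H(X))/log s

where s is the number of possible states (2 or 3 here), making every index
independent of the logarithm base.  0 * log 0 is 0 throughout.

Five discrete state definitions are supported:

========== ======= =========== ==================================== ===========
name       states  reference   state breaks (x reference)           excludes
========== ======= =========== ==================================== ===========
COL_wd       2     none        dry (A = 0) / wet (A > 0)            nothing
COL_ANa      3     mean        0.3, 1.7 (i.e. mean +/- 70%)         nothing
COL_ANw      3     wet mean    0.3, 1.7                             dry months
COL_MAXlin   3     max         1/3, 2/3                             nothing
COL_MAXg     3     max         1/4, 2/4                             nothing
========== ======= =========== ==================================== ===========

The middle state is closed on both ends (break values belong to s2).

State assignment is interval-safe: a monthly value is tabulated only when the
state computed from ``area`` and from ``area_max`` (clouds counted as water)
agree, i.e. cloud cover could not have changed the state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, InputError
from .timeseries import PondSeries, max_area, mean_area, monthly_series

N_MONTHS = 12

#: Half-width of the relative neighborhood around the mean (AN models).
DEFAULT_NEIGHBORHOOD = 0.7

EXCLUDED = None  # sentinel returned by assign_state


@dataclass(frozen=True)
class StateModelSpec:
    """How a continuous area is discretized into states."""

    name: str
    n_states: int
    reference: str | None  # "mean" | "max" | None
    thresholds: tuple[float, ...]  # break fractions of the reference
    exclude_dry: bool = False

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3):
            raise InputError("only 2- or 3-state models are supported")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise InputError("thresholds must be strictly increasing")


def model_specs(neighborhood: float = DEFAULT_NEIGHBORHOOD) -> dict[str, StateModelSpec]:
    """The five supported discrete model specifications."""
    lo, hi = 1.0 - neighborhood, 1.0 + neighborhood
    return {
        "COL_wd": StateModelSpec("COL_wd", 2, None, ()),
        "COL_ANa": StateModelSpec("COL_ANa", 3, "mean", (lo, hi)),
        "COL_ANw": StateModelSpec("COL_ANw", 3, "mean", (lo, hi), exclude_dry=True),
        "COL_MAXlin": StateModelSpec("COL_MAXlin", 3, "max", (1 / 3, 2 / 3)),
        "COL_MAXg": StateModelSpec("COL_MAXg", 3, "max", (1 / 4, 2 / 4)),
    }


DISCRETE_MODELS = tuple(model_specs())


@dataclass
class ContingencyTable:
    """state x month count table; rows are states s1..sn, columns Jan..Dec."""

    counts: np.ndarray
    pond_id: int | None = None
    model: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_MONTHS:
            raise InputError("contingency table must be n_states x 12")
        if (self.counts < 0).any():
            raise InputError("contingency counts must be non-negative")

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ColwellResult:
    constancy: float
    contingency: float
    predictability: float
    table: ContingencyTable


@dataclass(frozen=True)
class PredictabilityEstimate:
    """pond x model scalar, with the Colwell components when applicable."""

    pond_id: int
    model: str
    predictability: float
    constancy: float | None = None
    contingency: float | None = None
    n_used: int = 0


def _state_of(area: float, spec: StateModelSpec, reference_value: float | None) -> int:
    if spec.n_states == 2:
        return 0 if area == 0 else 1
    t1, t2 = (b * reference_value for b in spec.thresholds)
    if area < t1:
        return 0
    if area <= t2:  # middle state closed on both ends
        return 1
    return 2


def assign_state(area: float, area_max: float, spec: StateModelSpec,
                 reference_value: float | None = None):
    """State index for an [area, area_max] interval, or EXCLUDED (None).

    Returns the common state when cloud cover cannot change the outcome
    (both interval ends land in the same state), otherwise EXCLUDED.
    """
    if area > area_max:
        raise InputError("area must not exceed area_max")
    if spec.reference is not None:
        if reference_value is None or reference_value <= 0:
            raise InputError(f"{spec.name} needs a positive reference value")
    lo = _state_of(area, spec, reference_value)
    hi = _state_of(area_max, spec, reference_value)
    return lo if lo == hi else EXCLUDED


def build_table(series: PondSeries, spec: StateModelSpec,
                reference_value: float | None = None) -> ContingencyTable:
    """Tabulate monthly states across years (years are replicates).

    Monthly aggregates come from :func:`monthly_series`; interval-unsafe
    months are excluded.  For dry-excluding models, dry months (area = 0)
    are dropped before tabulation.
    """
    counts = np.zeros((spec.n_states, N_MONTHS), dtype=np.int64)
    for mv in monthly_series(series):
        if spec.exclude_dry and mv.area == 0:
            # Certainly or possibly dry: either way it cannot enter a
            # wet-only table with a trusted state.
            continue
        state = assign_state(mv.area, mv.area_max, spec, reference_value)
        if state is EXCLUDED:
            continue
        counts[state, mv.month - 1] += 1
    if counts.sum() == 0:
        raise EstimationError(
            f"pond {series.pond_id}: every monthly value was excluded under {spec.name}"
        )
    return ContingencyTable(counts, pond_id=series.pond_id, model=spec.name)


def colwell_metrics(table: ContingencyTable) -> ColwellResult:
    """Constancy, contingency and predictability of a contingency table."""
    counts = table.counts
    z = counts.sum()
    if z < 1:
        raise InputError("contingency table has zero total")
    s = table.n_states

    def entropy(values: np.ndarray) -> float:
        p = values[values > 0] / z
        return float(-(p * np.log(p)).sum())

    hx = entropy(counts.sum(axis=0))   # months
    hy = entropy(counts.sum(axis=1))   # states
    hxy = entropy(counts.ravel())
    log_s = np.log(s)
    constancy = 1.0 - hy / log_s
    contingency = (hx + hy - hxy) / log_s
    # Guard against -0.0 / tiny negative round-off.
    constancy = min(1.0, max(0.0, constancy))
    contingency = min(1.0, max(0.0, contingency))
    predictability = constancy + contingency
    return ColwellResult(constancy, contingency, min(1.0, predictability), table)


def run_discrete_model(series: PondSeries, name: str,
                       neighborhood: float = DEFAULT_NEIGHBORHOOD) -> PredictabilityEstimate:
    """Resolve the model's reference value, tabulate, and score one pond."""
    specs = model_specs(neighborhood)
    if name not in specs:
        raise InputError(f"unknown discrete model {name!r}; choose from {sorted(specs)}")
    spec = specs[name]
    reference = None
    if spec.reference == "mean":
        reference = mean_area(series, exclude_zeros=spec.exclude_dry)
    elif spec.reference == "max":
        reference = max_area(series)
    table = build_table(series, spec, reference)
    result = colwell_metrics(table)
    return PredictabilityEstimate(
        pond_id=series.pond_id,
        model=name,
        predictability=result.predictability,
        constancy=result.constancy,
        contingency=result.contingency,
        n_used=table.total,
    )
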