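"""Medium-constrained FBA and single-omission performance evaluation.

A model's predictive quality is scored by simulating growth on a defined
basal medium and on that medium with one component omitted at a time.  Each
omission is compared with the observed in-vivo phenotype: growth both in
vivo and in silico is a true positive (TP), no growth in both a true
negative (TN), in-silico-only growth a false positive (FP) and
in-vivo-only growth a false negative (FN).  A simulated growth rate below
10% of the basal rate counts as no growth.  Confusion-matrix metrics:

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)        NPV         = TN/(TN+FN)
    accuracy    = (TP+TN)/total     F = 2·precision·sensitivity/(precision+sensitivity)

FBA itself maximises the objective flux subject to steady-state mass
balance S·v = 0 and flux bounds, solved with the HiGHS linear-programming
backend.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .core import MetabolicNetwork, ReactionClass

__all__ = [
    "Medium",
    "MediumComponent",
    "OmissionOutcome",
    "PerformanceMetrics",
    "FBAResult",
    "fba",
    "apply_medium",
    "single_omission",
    "performance_metrics",
]

# growth below this is numerically zero, applied before the 10% rule
GROWTH_EPS = 1e-9
# no-growth threshold as a fraction of basal growth
NO_GROWTH_FRACTION = 0.10
# uptake cap used when a medium file omits a rate
DEFAULT_UPTAKE = 10.0


@dataclass
class MediumComponent:
    compound: str            # core id of the nutrient
    exchange_id: str         # exchange reaction providing it
    max_uptake: float = DEFAULT_UPTAKE


@dataclass
class Medium:
    name: str
    components: list[MediumComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.components:
            if c.max_uptake < 0:
                raise ValueError(
                    f"medium {self.name}: negative uptake for {c.compound}"
                )

    def without(self, compound: str) -> "Medium":
        return Medium(
            name=f"{self.name}-minus-{compound}",
            components=[c for c in self.components if c.compound != compound],
        )

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "Medium":
        """Load a medium table: compound, exchange id, optional max uptake."""
        path = Path(path)
        comps = []
        for line in path.read_text().splitlines():
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            rate = (
                float(parts[2])
                if len(parts) > 2 and parts[2].strip()
                else DEFAULT_UPTAKE
            )
            comps.append(MediumComponent(parts[0].strip(), parts[1].strip(), rate))
        return cls(name=name or path.stem, components=comps)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# compound\texchange\tmax_uptake"]
        for c in self.components:
            lines.append(f"{c.compound}\t{c.exchange_id}\t{c.max_uptake:g}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class FBAResult:
    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible


class FBAError(RuntimeError):
    pass


def fba(net: MetabolicNetwork, objective: str | None = None) -> FBAResult:
    """Maximise the objective flux subject to S·v = 0 and flux bounds.

    Infeasible problems return growth 0 with status ``infeasible``; an
    unbounded objective raises, naming the objective reaction.
    """
    objective = objective or net.objective_reaction
    if objective is None or objective not in net.reactions:
        raise FBAError(f"objective reaction {objective!r} not in network")
    rids = sorted(net.reactions)
    mets = sorted({m for r in net.reactions.values() for m in r.stoichiometry})
    met_idx = {m: i for i, m in enumerate(mets)}
    n, k = len(mets), len(rids)
    S = np.zeros((n, k))
    bounds = []
    c = np.zeros(k)
    for j, rid in enumerate(rids):
        r = net.reactions[rid]
        for met, coeff in r.stoichiometry.items():
            S[met_idx[met], j] = coeff
        bounds.append((r.lower_bound, r.upper_bound))
        if rid == objective:
            c[j] = -1.0  # linprog minimises
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(n),
        bounds=bounds,
        method="highs",
    )
    if res.status == 3:
        raise FBAError(f"FBA unbounded in the direction of objective {objective}")
    if res.status != 0:
        return FBAResult(0.0, {}, "infeasible")
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(rids)}
    return FBAResult(float(-res.fun), fluxes, "optimal")


def apply_medium(
    net: MetabolicNetwork, medium: Medium, log: list[str] | None = None
) -> MetabolicNetwork:
    """Return a copy of the network constrained to the given medium.

    Uptake bounds of exchanges listed in the medium are opened to the
    component's maximum rate; the uptake side of every other exchange is
    closed.  Secretion bounds are untouched.  Components whose exchange id
    is missing from the network are skipped with a warning.
    """
    out = net.copy()
    wanted: dict[str, float] = {}
    for comp in medium.components:
        if comp.exchange_id not in out.reactions:
            if log is not None:
                log.append(
                    f"medium {medium.name}: exchange {comp.exchange_id} "
                    f"({comp.compound}) not in network; skipped"
                )
            continue
        wanted[comp.exchange_id] = comp.max_uptake
    for rid, r in out.reactions.items():
        if r.rclass != ReactionClass.EXCHANGE:
            continue
        (met, coeff), = r.stoichiometry.items()
        rate = wanted.get(rid, 0.0)
        if coeff < 0:
            # written as "met -> (boundary)": uptake is negative flux
            r.lower_bound = -rate
        else:
            # written as "(boundary) -> met": uptake is positive flux
            r.upper_bound = rate
    return out


@dataclass
class OmissionOutcome:
    compound: str
    in_vivo_growth: bool
    in_silico_rate: float
    in_silico_growth: bool
    label: str  # TP | TN | FP | FN


def _label(in_vivo: bool, in_silico: bool) -> str:
    if in_vivo and in_silico:
        return "TP"
    if not in_vivo and not in_silico:
        return "TN"
    if not in_vivo and in_silico:
        return "FP"
    return "FN"


def load_phenotypes(path: str | Path) -> dict[str, bool]:
    """Read an in-vivo growth table CSV: compound, growth yes/no."""
    out: dict[str, bool] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if row[0].strip().lower() in ("compound", "omitted"):
                continue
            out[row[0].strip()] = row[1].strip().lower() in (
                "yes", "y", "1", "true", "growth",
            )
    return out


def single_omission(
    net: MetabolicNetwork,
    basal: Medium,
    compounds: list[str],
    in_vivo: dict[str, bool],
    objective: str | None = None,
) -> list[OmissionOutcome]:
    """Run leave-one-out growth simulations against in-vivo phenotypes.

    For each compound the basal medium is re-applied without that single
    component and FBA re-run; in-silico growth is called when the rate is
    at least 10% of the basal rate.  Aborts when the model cannot grow on
    the full basal medium, since the threshold is then undefined.
    """
    basal_result = fba(apply_medium(net, basal), objective)
    basal_rate = basal_result.objective_value
    if basal_rate <= GROWTH_EPS:
        raise FBAError(
            "no growth on the basal medium: the 10% no-growth threshold "
            "is undefined"
        )
    threshold = NO_GROWTH_FRACTION * basal_rate
    outcomes = []
    for compound in compounds:
        if compound not in in_vivo:
            raise KeyError(f"no in-vivo phenotype recorded for {compound!r}")
        result = fba(apply_medium(net, basal.without(compound)), objective)
        rate = result.objective_value
        if rate < GROWTH_EPS:
            rate = 0.0
        grows = rate >= threshold
        outcomes.append(
            OmissionOutcome(
                compound=compound,
                in_vivo_growth=in_vivo[compound],
                in_silico_rate=rate,
                in_silico_growth=grows,
                label=_label(in_vivo[compound], grows),
            )
        )
    return outcomes


@dataclass
class PerformanceMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    accuracy: float
    f_score: float

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "NPV": self.npv,
            "accuracy": self.accuracy,
            "F_score": self.f_score,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def performance_metrics(
    outcomes: list[OmissionOutcome] | tuple[int, int, int, int],
) -> PerformanceMetrics:
    """Confusion-matrix metrics from omission outcomes (or raw counts).

    Zero-denominator ratios are reported as NaN.
    """
    if isinstance(outcomes, tuple):
        tp, tn, fp, fn = outcomes
    else:
        tp = sum(1 for o in outcomes if o.label == "TP")
        tn = sum(1 for o in outcomes if o.label == "TN")
        fp = sum(1 for o in outcomes if o.label == "FP")
        fn = sum(1 for o in outcomes if o.label == "FN")
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    accuracy = _safe_div(tp + tn, tp + tn + fp + fn)
    if (
        math.isnan(precision)
        or math.isnan(sensitivity)
        or precision + sensitivity == 0
    ):
        f_score = math.nan
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    return PerformanceMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sensitivity, specificity=specificity,
        precision=precision, npv=npv, accuracy=accuracy, f_score=f_score,
    )
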