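"""Dual-label (13C/15N) stable-isotope bookkeeping.

Implements the accounting chain of a pulse-chase tracer study: delta
notation <-> isotope ratio <-> atom percent algebra, linear standard-curve
calibration of measured delta values against certified reference
materials, excess enrichment against unlabelled controls, element
quantification from a thermal-conductivity detector trace, aggregation of
fatty-acid biomarkers (PLFA/NLFA) into microbial pools, fungal-to-bacterial
ratios, and root-scaled partitioning of labelled carbon over the bacterial,
fungal and mycorrhizal channels of the soil food web.

Conventions: delta values are per mil against VPDB (carbon) or atmospheric
N2 (nitrogen); atom percent is the heavy isotope's share of all atoms of
the element, 100 * heavy / (heavy + light); excess is labelled minus
control atom percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BiomarkerMap,
    IsotopeMeasurement,
    ValidationError,
    measurements_frame,
)

logger = logging.getLogger("soilweb")

#: 13C/12C of the VPDB scale and 15N/14N of atmospheric N2 (IAEA values).
R_VPDB = 0.0111802
R_AIR_N2 = 0.0036765


@dataclass(frozen=True)
class ReferenceRatios:
    """Heavy/light reference ratios anchoring the delta scales."""

    R_VPDB: float = R_VPDB
    R_airN2: float = R_AIR_N2

    def __post_init__(self) -> None:
        if self.R_VPDB <= 0 or self.R_airN2 <= 0:
            raise ValidationError("reference ratios must be positive")

    def for_element(self, element: str) -> float:
        if element == "C":
            return self.R_VPDB
        if element == "N":
            return self.R_airN2
        raise ValidationError(f"unknown element {element!r}")


#: Certified delta values of the calibration reference materials.
DEFAULT_STANDARDS: dict[str, dict[str, float]] = {
    "USGS40": {"C": -26.39, "N": -4.52},
    "USGS41": {"C": 37.63, "N": 47.57},
    "NIST8542": {"C": -10.45},
    "USGS25": {"N": -30.41},
}

#: Element contents of the compounds used for the TCD mass standard curve.
DEFAULT_ELEMENT_STANDARDS: dict[str, dict[str, float]] = {
    "sulfanilamide": {"C": 41.84, "N": 16.27},
    "nicotinamide": {"C": 59.01, "N": 22.94},
    "L-aspartic acid": {"C": 36.09, "N": 10.52},
}


@dataclass
class StandardSet:
    """Certified isotope reference materials, keyed by name and element."""

    certified: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STANDARDS.items()})

    def delta(self, name: str, element: str) -> float:
        try:
            return self.certified[name][element]
        except KeyError as err:
            raise ValidationError(
                f"no certified delta for standard {name!r}, element {element!r}"
            ) from err

    def for_element(self, element: str) -> dict[str, float]:
        return {name: vals[element] for name, vals in self.certified.items()
                if element in vals}


# ---------------------------------------------------------------------------
# Delta / ratio / atom percent algebra
# ---------------------------------------------------------------------------

def delta_from_ratio(r_sample: float, r_ref: float) -> float:
    """Per-mil delta of a sample ratio against a reference ratio."""
    if r_sample <= 0 or r_ref <= 0:
        raise ValidationError("isotope ratios must be positive")
    return (r_sample / r_ref - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_ref: float) -> float:
    """Heavy/light ratio recovered from a per-mil delta value."""
    if r_ref <= 0:
        raise ValidationError("reference ratio must be positive")
    if delta <= -1000.0:
        raise ValidationError("delta below -1000 permil has no valid ratio")
    return r_ref * (delta / 1000.0 + 1.0)


def atom_percent(heavy: float, light: float) -> float:
    """Atom percent of the heavy isotope: 100 * heavy / (heavy + light)."""
    if light <= 0:
        raise ValidationError("light-isotope amount must be positive")
    if heavy < 0:
        raise ValidationError("heavy-isotope amount must be non-negative")
    return 100.0 * heavy / (heavy + light)


def atom_percent_from_ratio(r: float) -> float:
    """Atom percent from a heavy/light ratio: 100 * R / (1 + R)."""
    if r <= 0:
        raise ValidationError("isotope ratio must be positive")
    return 100.0 * r / (1.0 + r)


def ratio_from_atom_percent(ap: float) -> float:
    if not 0.0 < ap < 100.0:
        raise ValidationError("atom percent must be in (0, 100) for a ratio")
    return ap / (100.0 - ap)


def delta_to_atom_percent(delta: float, r_ref: float) -> float:
    """Atom percent via R = R_ref * (delta/1000 + 1)."""
    return atom_percent_from_ratio(ratio_from_delta(delta, r_ref))


def atom_percent_to_delta(ap: float, r_ref: float) -> float:
    return delta_from_ratio(ratio_from_atom_percent(ap), r_ref)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Least-squares line mapping measured delta to the certified scale."""

    slope: float
    intercept: float
    standards: list[tuple[str, float, float]]  # (name, measured, certified)

    def apply(self, measured):
        return self.slope * np.asarray(measured, dtype=float) + self.intercept

    def residuals(self) -> np.ndarray:
        m = np.array([s[1] for s in self.standards])
        c = np.array([s[2] for s in self.standards])
        return c - self.apply(m)


def calibrate(measured: Sequence[tuple[str, float]],
              standards: StandardSet | Mapping[str, float] | None = None,
              element: str = "C") -> CalibrationCurve:
    """Fit certified = slope * measured + intercept by ordinary least squares.

    ``measured`` pairs standard names with their measured delta values;
    certified values come from ``standards`` (defaults to the USGS/NIST
    set). With exactly two standards this is the exact two-point line, so
    applying the curve at each standard reproduces its certified value.
    """
    if standards is None:
        standards = StandardSet()
    if isinstance(standards, StandardSet):
        certified_map = standards.for_element(element)
    else:
        certified_map = dict(standards)
    pairs = []
    for name, meas in measured:
        if name not in certified_map:
            raise ValidationError(
                f"standard {name!r} has no certified value for element {element!r}")
        pairs.append((name, float(meas), float(certified_map[name])))
    if len(pairs) < 2:
        raise ValidationError("calibration needs at least 2 standards")
    x = np.array([p[1] for p in pairs])
    y = np.array([p[2] for p in pairs])
    if np.ptp(x) == 0:
        raise ValidationError("calibration standards have identical measured values")
    slope, intercept = np.polyfit(x, y, 1)
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            standards=pairs)


# ---------------------------------------------------------------------------
# Excess enrichment and element content
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Excess:
    """Atom percent excess of a labelled sample over its control."""

    value: float
    below_control: bool


def excess_atom_percent(labelled: float, control: float) -> Excess:
    """Labelled minus control atom percent; negative excess is flagged.

    A value below the control is measurement noise around zero enrichment;
    it is preserved (not clipped) here so budgets stay honest, and only
    floored later when fractions are formed.
    """
    for v, what in ((labelled, "labelled"), (control, "control")):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{what} atom percent outside [0, 100]: {v}")
    diff = labelled - control
    if diff < 0:
        logger.debug("excess below control: %.6g - %.6g = %.6g",
                     labelled, control, diff)
    return Excess(value=diff, below_control=diff < 0)


@dataclass
class ElementContentCurve:
    """Linear TCD standard curve: element mass (ug) as a function of area."""

    slope: float
    intercept: float

    def mass_ug(self, area) -> np.ndarray | float:
        out = self.slope * np.asarray(area, dtype=float) + self.intercept
        return float(out) if np.isscalar(area) else out


def element_content_curve(points: Sequence[tuple[float, float]]) -> ElementContentCurve:
    """Fit the detector-area -> element-mass line from standard weighings.

    Each point is (detector area, known element mass in ug); the known mass
    of a weighed compound standard is sample mass x %element / 100.
    """
    if len(points) < 2:
        raise ValidationError("element standard curve needs at least 2 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("degenerate standard curve: identical areas")
    slope, intercept = np.polyfit(x, y, 1)
    return ElementContentCurve(slope=float(slope), intercept=float(intercept))


def standard_element_mass(compound: str, sample_mass_ug: float,
                          element: str = "C") -> float:
    """Element mass contributed by a weighed standard compound."""
    try:
        pct = DEFAULT_ELEMENT_STANDARDS[compound][element]
    except KeyError as err:
        raise ValidationError(
            f"unknown element standard {compound!r} / element {element!r}") from err
    return sample_mass_ug * pct / 100.0


# ---------------------------------------------------------------------------
# Lipid biomarker aggregation
# ---------------------------------------------------------------------------

def aggregate_pools(fa_table: pd.DataFrame,
                    biomarkers: BiomarkerMap | None = None) -> pd.DataFrame:
    """Sum fatty-acid concentrations and excess 13C into microbial pools.

    ``fa_table`` needs columns ``fatty_acid``, ``assay`` (PLFA/NLFA),
    ``concentration`` and ``excess_13c``. Unmapped fatty acids are dropped
    with a logged warning (general lipids carry no taxonomic signal). The
    returned frame is indexed by pool with summed columns plus each pool's
    percentage share of the total excess 13C over all mapped biomarkers.
    """
    if biomarkers is None:
        biomarkers = BiomarkerMap()
    required = {"fatty_acid", "assay", "concentration", "excess_13c"}
    missing = required - set(fa_table.columns)
    if missing:
        raise ValidationError(f"fatty-acid table missing columns {sorted(missing)}")
    pools = [biomarkers.pool_of(a, f)
             for a, f in zip(fa_table["assay"], fa_table["fatty_acid"])]
    mapped = pd.Series(pools, index=fa_table.index)
    unmapped = fa_table.loc[mapped.isna(), "fatty_acid"]
    if not unmapped.empty:
        logger.warning("ignoring unmapped fatty acids: %s",
                       ", ".join(sorted(set(unmapped))))
    work = fa_table.loc[mapped.notna()].assign(pool=mapped.dropna())
    if work.empty:
        raise ValidationError("no fatty acid matched the biomarker map")
    agg = work.groupby("pool")[["concentration", "excess_13c"]].sum()
    total_excess = agg["excess_13c"].sum()
    if total_excess > 0:
        agg["pct_of_excess"] = 100.0 * agg["excess_13c"] / total_excess
    else:
        agg["pct_of_excess"] = 0.0
    return agg


def fb_ratio(fungal: float, bacterial: float) -> float:
    """Fungal-to-bacterial ratio of biomass or excess 13C."""
    if bacterial <= 0:
        raise ValidationError("bacterial amount must be positive for F:B ratio")
    if fungal < 0:
        raise ValidationError("fungal amount must be non-negative")
    return fungal / bacterial


def fb_ratio_samples(pairs: Sequence[tuple[float, float]]) -> dict[str, float]:
    """Per-sample F:B ratios summarised as mean and standard deviation.

    The mean of per-sample ratios is generally not the ratio of pooled
    sums; both are reported so the distinction stays visible.
    """
    if not pairs:
        raise ValidationError("no samples given")
    ratios = np.array([fb_ratio(f, b) for f, b in pairs])
    fungal_sum = sum(f for f, _ in pairs)
    bact_sum = sum(b for _, b in pairs)
    return {
        "mean": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        "pooled": fb_ratio(fungal_sum, bact_sum),
        "n": len(ratios),
    }


# ---------------------------------------------------------------------------
# Carbon-channel partitioning
# ---------------------------------------------------------------------------

@dataclass
class TracerBudget:
    """Per-pool excess label with channel fractions and root-scaled values.

    ``fractions`` are each pool's share of the summed (floored) excess over
    the pools included and sum to one; ``root_scaled`` divides each pool's
    excess by the total labelled carbon in the roots instead, the scaling
    that makes stages with different root label uptake comparable.
    """

    excess: dict[str, float]
    fractions: dict[str, float]
    root_scaled: dict[str, float]
    root_excess: float
    floored_pools: list[str]

    def to_frame(self) -> pd.DataFrame:
        pools = list(self.excess)
        return pd.DataFrame({
            "pool": pools,
            "excess": [self.excess[p] for p in pools],
            "fraction": [self.fractions[p] for p in pools],
            "root_scaled": [self.root_scaled[p] for p in pools],
            "floored": [p in self.floored_pools for p in pools],
        })


def channel_partition(pool_excess: Mapping[str, float],
                      root_excess: float) -> TracerBudget:
    """Partition labelled carbon over food-web channels.

    Negative pool excess (label below control) is floored to zero before
    fractions are formed, with the flooring recorded; the raw value is kept
    in ``excess``. Fractions are pool / sum(pools); root-scaled values are
    pool / root_excess.
    """
    if root_excess <= 0:
        raise ValidationError("root excess must be positive")
    if not pool_excess:
        raise ValidationError("no pools given")
    floored = [p for p, v in pool_excess.items() if v < 0]
    for p in floored:
        logger.info("flooring negative excess of pool %r (%.6g) to 0",
                    p, pool_excess[p])
    clipped = {p: max(0.0, float(v)) for p, v in pool_excess.items()}
    total = sum(clipped.values())
    if total <= 0:
        raise ValidationError("all pool excess values are <= 0")
    return TracerBudget(
        excess=dict(pool_excess),
        fractions={p: v / total for p, v in clipped.items()},
        root_scaled={p: v / root_excess for p, v in clipped.items()},
        root_excess=float(root_excess),
        floored_pools=floored,
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

#: Which chase time point each compartment class is reported at: microbial
#: pools the day after the pulse, their consumers after one week, predators
#: after two -- the time of peak label incorporation for each trophic level.
DEFAULT_TIME_POINTS: dict[str, str] = {
    "roots": "1d",
    "bacteria": "1d", "fungi": "1d", "AMF": "1d", "actinomycetes": "1d",
    "bacterivorous_nematodes": "1w", "fungivorous_nematodes": "1w",
    "fungivorous_mites": "1w", "collembola": "1w", "earthworms": "1w",
    "enchytraeids": "1w", "root_feeding_nematodes": "1w",
    "predaceous_mites": "2w", "spiders": "2w", "omnivorous_nematodes": "2w",
}

MICROBIAL_POOLS = ("bacteria", "fungi", "AMF")


class TracerExperiment:
    """Pulse-chase tracer experiment: measurements in, carbon budget out.

    Parameters
    ----------
    measurements : iterable of IsotopeMeasurement
        Labelled and control atom-percent (or delta) observations per
        compartment, element, time point and replicate.
    references : ReferenceRatios
        Scale anchors used to convert delta values to atom percent.
    time_points : mapping
        Compartment -> chase time point at which it is evaluated.
    root_compartment : str
        Compartment whose excess scales the budget (default ``roots``).
    """

    def __init__(self, measurements: Iterable[IsotopeMeasurement],
                 references: ReferenceRatios | None = None,
                 time_points: Mapping[str, str] | None = None,
                 root_compartment: str = "roots"):
        self.measurements = list(measurements)
        if not self.measurements:
            raise ValidationError("no measurements given")
        self.references = references or ReferenceRatios()
        self.time_points = dict(time_points or DEFAULT_TIME_POINTS)
        self.root_compartment = root_compartment

    def _atom_percent_frame(self) -> pd.DataFrame:
        df = measurements_frame(self.measurements)
        refs = self.references

        def to_ap(row) -> float:
            if row.value_kind == "atom_percent":
                return row.value
            r_ref = refs.for_element(row.element)
            if row.value_kind == "delta_permil":
                return delta_to_atom_percent(row.value, r_ref)
            return atom_percent_from_ratio(row.value)

        df["atom_percent"] = [to_ap(r) for r in df.itertuples(index=False)]
        return df

    def excess_table(self, element: str = "C") -> pd.DataFrame:
        """Mean excess atom percent per compartment and time point.

        Labelled replicates are averaged and the mean control of the same
        compartment/time point is subtracted. Negative means are flagged,
        not clipped.
        """
        df = self._atom_percent_frame()
        df = df[df["element"] == element]
        if df.empty:
            raise ValidationError(f"no measurements for element {element!r}")
        keys = ["compartment", "time_point"]
        mean_ap = (df.groupby([*keys, "treatment"])["atom_percent"]
                   .mean().unstack("treatment"))
        for needed in ("labelled", "control"):
            if needed not in mean_ap.columns:
                raise ValidationError(
                    f"missing {needed!r} measurements for element {element!r}")
        missing = mean_ap.index[mean_ap.isna().any(axis=1)]
        if len(missing):
            raise ValidationError(
                f"compartments lacking labelled or control data: {list(missing)}")
        out = mean_ap.reset_index()
        out["excess"] = out["labelled"] - out["control"]
        out["below_control"] = out["excess"] < 0
        return out

    def fit(self, element: str = "C",
            pools: Sequence[str] = MICROBIAL_POOLS) -> "TracerResults":
        """Compute the carbon budget: per-compartment excess, channel
        fractions for the microbial pools, root-scaled values, F:B ratio."""
        table = self.excess_table(element=element)

        def excess_at(compartment: str) -> float | None:
            tp = self.time_points.get(compartment)
            sel = table[table["compartment"] == compartment]
            if tp is not None:
                at_tp = sel[sel["time_point"] == tp]
                sel = at_tp if not at_tp.empty else sel
            if sel.empty:
                return None
            return float(sel["excess"].iloc[0])

        root_excess = excess_at(self.root_compartment)
        if root_excess is None:
            raise ValidationError(
                f"root compartment {self.root_compartment!r} not measured")
        pool_excess = {}
        for p in pools:
            v = excess_at(p)
            if v is not None:
                pool_excess[p] = v
        if not pool_excess:
            raise ValidationError("none of the requested pools were measured")
        budget = channel_partition(pool_excess, root_excess)

        fb = None
        if "fungi" in pool_excess and "bacteria" in pool_excess \
                and pool_excess["bacteria"] > 0:
            fb = fb_ratio(max(pool_excess["fungi"], 0.0), pool_excess["bacteria"])
        return TracerResults(model=self, element=element,
                             excess=table, budget=budget, fb=fb)


class TracerResults:
    """Fitted tracer budget with per-compartment excess enrichment."""

    def __init__(self, model: TracerExperiment, element: str,
                 excess: pd.DataFrame, budget: TracerBudget,
                 fb: float | None):
        self.model = model
        self.element = element
        self.excess = excess
        self.budget = budget
        self.fb_ratio = fb

    def budget_frame(self) -> pd.DataFrame:
        return self.budget.to_frame()

    def summary(self) -> str:
        lines = [f"Tracer budget ({self.element}), "
                 f"root excess = {self.budget.root_excess:.6g}"]
        lines.append(self.budget.to_frame().to_string(
            index=False, float_format=lambda v: f"{v:.4f}"))
        if self.fb_ratio is not None:
            lines.append(f"F:B ratio of excess label: {self.fb_ratio:.4f}")
        if self.budget.floored_pools:
            lines.append("pools floored at zero for partitioning: "
                         + ", ".join(self.budget.floored_pools))
        return "\n".join(lines)
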