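"""Synthetic communities and tracer experiments with known ground truth.

The community generator emulates the sampling design of a three-stage
chronosequence (3 sites per stage, 3 subplots per site, so 9 samples per
stage) and plants a tunable amount of co-occurrence structure: taxa within
a functional block share a latent per-sample effect, so their pairwise
Spearman correlation can be dialled per stage. Because Spearman
correlation is invariant under monotone marginal transforms, the latent
Gaussian copula is mapped through a lognormal marginal to get
abundance-like values, and the population Spearman target rho is hit by
setting the latent Pearson correlation to r = 2 sin(pi * rho / 6).

Occupancy (the probability a taxon is detected in a sample) is modelled as
left-censoring at a detection limit: a taxon's lowest latent values become
zeros. Censoring is driven by the same latent variable, so presence-absence
patterns inherit the block structure -- which is what makes the
presence-absence robustness check meaningful.

The tracer generator emits labelled and control atom-percent measurements
for a pulse-chase design with known transfer fractions, so the channel
partitioning can be validated by recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import STAGES, AbundanceTable, IsotopeMeasurement, ValidationError
from .isotope import R_AIR_N2, R_VPDB, delta_to_atom_percent


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation giving Spearman rho_s for a Gaussian copula."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


# ---------------------------------------------------------------------------
# Community generator
# ---------------------------------------------------------------------------

#: Default functional blocks: (subgroup, n_taxa, main group, trophic function).
DEFAULT_GROUPS: tuple[tuple[str, int, str, str], ...] = (
    ("bacteria_copio", 7, "bacteria", "decomposer"),
    ("bacteria_oligo", 7, "bacteria", "decomposer"),
    ("fungi_sapro", 7, "fungi", "decomposer"),
    ("amf", 6, "AMF", "mutualist"),
    ("nematodes_bact", 6, "fauna", "bacterivore"),
    ("plants", 6, "plants", "primary_producer"),
)


@dataclass
class CommunitySpec:
    """Design of a synthetic successional community.

    ``rho_block`` is the target within-block Spearman correlation per
    stage; a monotone profile like (0.3, 0.7, 0.7) encodes the network
    "tightening" scenario of a recent -> mid transition with no further
    change. ``occupancy`` is the fraction of samples in which a taxon is
    detected (zeros are censored low values).
    """

    n_stages: int = 3
    sites_per_stage: int = 3
    subplots_per_site: int = 3
    groups: Sequence[tuple[str, int, str, str]] = DEFAULT_GROUPS
    rho_block: float | Sequence[float] = (0.3, 0.7, 0.7)
    occupancy: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_stages <= len(STAGES):
            raise ValidationError(
                f"n_stages must be between 1 and {len(STAGES)}")
        rho = self.rho_per_stage()
        if any(not 0.0 <= r <= 1.0 for r in rho):
            raise ValidationError("rho_block must lie in [0, 1]")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValidationError("occupancy must be in (0, 1]")
        if self.samples_per_stage < 2:
            raise ValidationError("need at least 2 samples per stage")

    @property
    def samples_per_stage(self) -> int:
        return self.sites_per_stage * self.subplots_per_site

    def rho_per_stage(self) -> list[float]:
        if np.isscalar(self.rho_block):
            return [float(self.rho_block)] * self.n_stages
        rho = [float(r) for r in self.rho_block]
        if len(rho) != self.n_stages:
            raise ValidationError(
                f"rho_block needs {self.n_stages} entries, got {len(rho)}")
        return rho


def generate_abundance(spec: CommunitySpec) -> AbundanceTable:
    """Draw a synthetic abundance table from a community design.

    Deterministic given ``spec.seed``: the same spec yields the same table.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.rho_per_stage()
    stages = STAGES[:spec.n_stages]
    n_samples = spec.samples_per_stage

    taxa, meta_rows = [], []
    for subgroup, n_taxa, main_group, trophic in spec.groups:
        for k in range(n_taxa):
            tid = f"{subgroup}_{k + 1:02d}"
            taxa.append(tid)
            meta_rows.append({"taxon_id": tid, "subgroup": subgroup,
                              "main_group": main_group,
                              "trophic_function": trophic})
    taxon_meta = pd.DataFrame(meta_rows).set_index("taxon_id")

    detection = stats.norm.ppf(1.0 - spec.occupancy) if spec.occupancy < 1 else -np.inf

    columns, sample_rows, blocks_by_stage = [], [], []
    values = np.zeros((len(taxa), spec.n_stages * n_samples))
    for s_idx, stage in enumerate(stages):
        r = _spearman_to_pearson(rho[s_idx])
        col0 = s_idx * n_samples
        for site in range(spec.sites_per_stage):
            for plot in range(spec.subplots_per_site):
                sid = f"{stage}-s{site + 1}-p{plot + 1}"
                columns.append(sid)
                sample_rows.append({"sample_id": sid,
                                    "site": f"{stage.upper()}{site + 1}",
                                    "subplot": plot + 1, "stage": stage})
        row = 0
        for subgroup, n_taxa, _, _ in spec.groups:
            latent = rng.standard_normal(n_samples)
            eps = rng.standard_normal((n_taxa, n_samples))
            z = np.sqrt(r) * latent + np.sqrt(1.0 - r) * eps
            abund = 100.0 * np.exp(z)
            abund[z < detection] = 0.0
            values[row:row + n_taxa, col0:col0 + n_samples] = abund
            row += n_taxa
        blocks_by_stage.append(stage)

    frame = pd.DataFrame(values, index=taxa, columns=columns)
    sample_meta = pd.DataFrame(sample_rows).set_index("sample_id")
    return AbundanceTable(values=frame, taxon_meta=taxon_meta,
                          sample_meta=sample_meta)


# ---------------------------------------------------------------------------
# Tracer generator
# ---------------------------------------------------------------------------

def _normalized(fractions: Mapping[str, float], what: str) -> dict[str, float]:
    vals = dict(fractions)
    if any(v < 0 for v in vals.values()):
        raise ValidationError(f"{what} fractions must be non-negative")
    total = sum(vals.values())
    if total <= 0:
        raise ValidationError(f"{what} fractions must not all be zero")
    return {k: v / total for k, v in vals.items()}


@dataclass
class TracerSpec:
    """Ground truth of a synthetic dual-label pulse-chase experiment.

    Microbial pools receive label the day after the pulse, consumers after
    one week, predators after two. ``*_fractions`` set how each trophic
    level's label splits over its compartments (normalised internally);
    the ``*_total`` values are total excess atom percent at that level.
    Defaults mirror a recently abandoned grassland where fungi take up
    about half the root-derived carbon.
    """

    root_excess: float = 0.8
    microbial_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"bacteria": 0.35, "fungi": 0.50, "AMF": 0.15})
    consumer_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "bacterivorous_nematodes": 0.30, "earthworms": 0.15,
            "fungivorous_nematodes": 0.25, "fungivorous_mites": 0.15,
            "collembola": 0.15})
    predator_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "predaceous_mites": 0.40, "spiders": 0.30,
            "omnivorous_nematodes": 0.30})
    microbial_total: float = 0.20
    consumer_total: float = 0.05
    predator_total: float = 0.02
    noise_sigma: float = 0.05
    n_replicates: int = 9
    baseline_delta13c: float = -27.0
    baseline_delta15n: float = 2.0
    include_nitrogen: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be non-negative")
        if self.root_excess <= 0:
            raise ValidationError("root excess must be positive")
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")
        for m, w in ((self.microbial_fractions, "microbial"),
                     (self.consumer_fractions, "consumer"),
                     (self.predator_fractions, "predator")):
            _normalized(m, w)

    def truth(self) -> dict:
        return {
            "root_excess": self.root_excess,
            "microbial_fractions": _normalized(self.microbial_fractions,
                                               "microbial"),
            "consumer_fractions": _normalized(self.consumer_fractions,
                                              "consumer"),
            "predator_fractions": _normalized(self.predator_fractions,
                                              "predator"),
            "microbial_total": self.microbial_total,
            "consumer_total": self.consumer_total,
            "predator_total": self.predator_total,
        }


def generate_tracer(spec: TracerSpec
                    ) -> tuple[list[IsotopeMeasurement], dict]:
    """Emit labelled and control atom-percent measurements plus ground truth.

    Labelled replicates carry the compartment's true excess multiplied by
    lognormal noise exp(N(0, sigma)) on top of the natural-abundance
    baseline; controls sit at the baseline. With sigma = 0 the pipeline
    must recover the transfer fractions exactly.
    """
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth()
    baseline_c = delta_to_atom_percent(spec.baseline_delta13c, R_VPDB)
    baseline_n = delta_to_atom_percent(spec.baseline_delta15n, R_AIR_N2)

    plan: list[tuple[str, str, float]] = [("roots", "1d", spec.root_excess)]
    for pool, f in truth["microbial_fractions"].items():
        plan.append((pool, "1d", f * spec.microbial_total))
    for comp, f in truth["consumer_fractions"].items():
        plan.append((comp, "1w", f * spec.consumer_total))
    for comp, f in truth["predator_fractions"].items():
        plan.append((comp, "2w", f * spec.predator_total))

    out: list[IsotopeMeasurement] = []

    def emit(element: str, baseline: float) -> None:
        for comp, tp, excess in plan:
            if element == "N" and comp in truth["microbial_fractions"]:
                continue  # lipid markers cannot split microbial 15N
            for rep in range(spec.n_replicates):
                noise = (np.exp(rng.normal(0.0, spec.noise_sigma))
                         if spec.noise_sigma > 0 else 1.0)
                out.append(IsotopeMeasurement(
                    compartment=comp, element=element, time_point=tp,
                    treatment="labelled", value=baseline + excess * noise,
                    value_kind="atom_percent", replicate=f"r{rep + 1}"))
                out.append(IsotopeMeasurement(
                    compartment=comp, element=element, time_point=tp,
                    treatment="control", value=baseline,
                    value_kind="atom_percent", replicate=f"r{rep + 1}"))

    emit("C", baseline_c)
    if spec.include_nitrogen:
        emit("N", baseline_n)
    return out, truth
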