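"""Shared domain types and tidy-TSV readers/writers.

The pipeline's interchange format is long ("tidy") tab-separated text: one
row per observation. Wide matrices (taxa x samples) are derived in memory.
Abundances may be in heterogeneous units per taxon group (sequence reads,
microscope counts, % plant cover); they are never compared across taxa
except through ranks, so no cross-taxon normalisation is applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("soilweb")

#: Closed vocabulary of successional stages (time since arable abandonment).
STAGES = ("recent", "mid", "long")

#: Default mapping of chronosequence site codes to successional stage.
DEFAULT_SITE_STAGES: dict[str, str] = {
    "OR": "recent", "REY": "recent", "TW": "recent",
    "MO": "mid", "NR": "mid", "WV": "mid",
    "MV": "long", "DK": "long", "BB": "long",
}


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


class SchemaError(ValidationError):
    """Raised when a required column is missing from an input file."""


# ---------------------------------------------------------------------------
# Abundance data
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Taxa x samples non-negative abundance matrix with annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative abundances, index = taxon ids, columns = sample ids.
    taxon_meta : pandas.DataFrame
        Per-taxon annotations indexed by taxon id, with columns
        ``subgroup``, ``main_group`` and ``trophic_function``.
    sample_meta : pandas.DataFrame
        Per-sample annotations indexed by sample id, with columns
        ``site``, ``subplot`` and ``stage`` (one of :data:`STAGES`).
    """

    values: pd.DataFrame
    taxon_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("abundance values must be finite")
        if (vals < 0).any():
            t, s = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance for taxon {self.values.index[t]!r} "
                f"in sample {self.values.columns[s]!r}"
            )
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("duplicate taxon or sample ids in matrix")
        if set(self.values.index) != set(self.taxon_meta.index):
            raise ValidationError("taxon ids in matrix and taxon_meta differ")
        if set(self.values.columns) != set(self.sample_meta.index):
            raise ValidationError("sample ids in matrix and sample_meta differ")
        for col in ("subgroup", "main_group", "trophic_function"):
            if col not in self.taxon_meta.columns:
                raise SchemaError(f"taxon_meta is missing column {col!r}")
        for col in ("site", "subplot", "stage"):
            if col not in self.sample_meta.columns:
                raise SchemaError(f"sample_meta is missing column {col!r}")
        bad = set(self.sample_meta["stage"]) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage label(s): {sorted(bad)}")
        counts = self.sample_meta["stage"].value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise ValidationError(
                f"stage(s) with fewer than 2 samples: {sorted(small.index)}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def stages(self) -> list[str]:
        return [s for s in STAGES if s in set(self.sample_meta["stage"])]

    def samples_of_stage(self, stage: str) -> list[str]:
        if stage not in set(self.sample_meta["stage"]):
            raise ValidationError(f"stage {stage!r} absent from table")
        mask = self.sample_meta["stage"] == stage
        # preserve matrix column order
        keep = set(self.sample_meta.index[mask])
        return [s for s in self.values.columns if s in keep]

    def subset(self, taxa: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "AbundanceTable":
        taxa = list(taxa) if taxa is not None else list(self.values.index)
        samples = list(samples) if samples is not None else list(self.values.columns)
        return AbundanceTable(
            values=self.values.loc[taxa, samples],
            taxon_meta=self.taxon_meta.loc[taxa],
            sample_meta=self.sample_meta.loc[samples],
        )

    def group_of(self, level: str = "subgroup") -> pd.Series:
        if level not in ("subgroup", "main_group"):
            raise ValueError(f"unknown grouping level {level!r}")
        return self.taxon_meta[level].reindex(self.values.index)


_ABUNDANCE_REQUIRED = ("taxon_id", "sample_id", "abundance")
_TAXON_COLS = ("subgroup", "main_group", "trophic_function")
_SAMPLE_COLS = ("site", "subplot", "stage")


def read_abundance(path: str | Path,
                   site_stages: Mapping[str, str] | None = None) -> AbundanceTable:
    """Read a tidy abundance TSV into an :class:`AbundanceTable`.

    The file must carry columns ``taxon_id``, ``sample_id``, ``abundance``
    plus the taxon annotations (``subgroup``, ``main_group``,
    ``trophic_function``) and sample annotations (``site``, ``subplot`` and
    either ``stage`` or a resolvable site code). ``site_stages`` maps site
    codes to stages when the ``stage`` column is absent; it defaults to the
    nine-field chronosequence assignment in :data:`DEFAULT_SITE_STAGES`.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in _ABUNDANCE_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["taxon_id", "sample_id"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ValidationError(f"{path}: duplicate (taxon, sample) pair at row {row}")
    neg = df["abundance"] < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0])
        raise ValidationError(f"{path}: negative abundance at row {row}")

    for col in _TAXON_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing taxon annotation column {col!r}")
    for col in ("site", "subplot"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing sample annotation column {col!r}")
    if "stage" not in df.columns:
        mapping = dict(site_stages or DEFAULT_SITE_STAGES)
        unknown = set(df["site"].astype(str)) - set(mapping)
        if unknown:
            raise ValidationError(
                f"{path}: site code(s) with no stage mapping: {sorted(unknown)}"
            )
        df = df.assign(stage=df["site"].astype(str).map(mapping))

    values = (
        df.pivot(index="taxon_id", columns="sample_id", values="abundance")
        .fillna(0.0)
        .astype(float)
    )
    taxon_meta = (
        df[["taxon_id", *_TAXON_COLS]].drop_duplicates("taxon_id")
        .set_index("taxon_id").reindex(values.index)
    )
    sample_meta = (
        df[["sample_id", *_SAMPLE_COLS]].drop_duplicates("sample_id")
        .set_index("sample_id").reindex(values.columns)
    )
    return AbundanceTable(values=values, taxon_meta=taxon_meta,
                          sample_meta=sample_meta)


def write_abundance(table: AbundanceTable, path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write an :class:`AbundanceTable` back to tidy long-format TSV."""
    long = (
        table.values.stack().rename("abundance").reset_index()
        .rename(columns={"level_0": "taxon_id", "level_1": "sample_id"})
    )
    long.columns = ["taxon_id", "sample_id", "abundance"]
    long = long.merge(table.taxon_meta, left_on="taxon_id", right_index=True)
    long = long.merge(table.sample_meta, left_on="sample_id", right_index=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        long.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Isotope measurements
# ---------------------------------------------------------------------------

ELEMENTS = ("C", "N")
TIME_POINTS = ("1d", "1w", "2w")
TREATMENTS = ("labelled", "control")
VALUE_KINDS = ("delta_permil", "atom_percent", "ratio")


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One compartment's isotopic state for one element and time point.

    ``value_kind`` distinguishes per-mil delta notation, atom percent of the
    heavy isotope, and a raw heavy/light isotope ratio. ``mass_ug`` is the
    optional mass of the element in the compartment (micrograms), used when
    converting intensive enrichment to element amounts.
    """

    compartment: str
    element: str
    time_point: str
    treatment: str
    value: float
    value_kind: str
    replicate: str | None = None
    mass_ug: float | None = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValidationError(f"unknown element {self.element!r}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        v = float(self.value)
        if not np.isfinite(v):
            raise ValidationError("isotope value must be finite")
        if self.value_kind == "atom_percent" and not 0.0 <= v <= 100.0:
            raise ValidationError(f"atom_percent outside [0, 100]: {v}")
        if self.value_kind == "ratio" and v <= 0:
            raise ValidationError(f"isotope ratio must be positive: {v}")
        if self.value_kind == "delta_permil" and v <= -1000.0:
            raise ValidationError(f"delta below -1000 permil: {v}")
        if self.mass_ug is not None and self.mass_ug < 0:
            raise ValidationError("element mass must be non-negative")


_ISOTOPE_REQUIRED = ("compartment", "element", "time_point", "treatment",
                     "value", "value_kind")


def read_isotope(path: str | Path) -> list[IsotopeMeasurement]:
    """Read a tidy isotope measurement TSV.

    Returns a validated list of :class:`IsotopeMeasurement`; an empty file
    yields an empty list with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in _ISOTOPE_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df.empty:
        logger.warning("%s: isotope file contains no measurements", path)
        return []
    out: list[IsotopeMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(IsotopeMeasurement(
                compartment=str(row.compartment),
                element=str(row.element),
                time_point=str(row.time_point),
                treatment=str(row.treatment),
                value=float(row.value),
                value_kind=str(row.value_kind),
                replicate=str(row.replicate) if hasattr(row, "replicate")
                and not pd.isna(row.replicate) else None,
                mass_ug=float(row.mass_ug) if hasattr(row, "mass_ug")
                and not pd.isna(row.mass_ug) else None,
            ))
        except ValidationError as err:
            raise ValidationError(f"{path}: row {i}: {err}") from err
    return out


def write_isotope(measurements: Iterable[IsotopeMeasurement],
                  path: str | Path,
                  header_comment: str | None = None) -> None:
    rows = []
    for m in measurements:
        rows.append({
            "compartment": m.compartment, "element": m.element,
            "time_point": m.time_point, "treatment": m.treatment,
            "value": m.value, "value_kind": m.value_kind,
            "replicate": m.replicate if m.replicate is not None else "",
            "mass_ug": m.mass_ug if m.mass_ug is not None else "",
        })
    df = pd.DataFrame(rows, columns=[*_ISOTOPE_REQUIRED, "replicate", "mass_ug"])
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def measurements_frame(measurements: Iterable[IsotopeMeasurement]) -> pd.DataFrame:
    """Tidy DataFrame view of a measurement list."""
    return pd.DataFrame([m.__dict__ for m in measurements])


# ---------------------------------------------------------------------------
# Lipid biomarkers
# ---------------------------------------------------------------------------

def normalize_fatty_acid(name: str) -> str:
    """Canonicalise a fatty-acid name (omega sign -> 'w', drop commas/dots)."""
    return (
        name.strip()
        .replace("ω", "w")  # omega
        .replace("Ω", "w")
        .replace("6,9", "6.9")
        .lower()
    )


#: Fatty-acid biomarkers of soil microbial pools. Phospholipid fatty acids
#: (PLFA) mark living bacterial, actinomycete and fungal membranes; the
#: neutral-lipid (NLFA) 16:1w5 marks arbuscular mycorrhizal storage lipids.
DEFAULT_BIOMARKERS: dict[tuple[str, str], str] = {
    **{("PLFA", normalize_fatty_acid(fa)): "bacteria" for fa in (
        "i14:0", "i15:0", "a15:0", "i16:0", "16:1w7t", "17:1w7",
        "a17:1w7", "i17:0", "cy17:0", "18:1w7c", "cy19:0")},
    ("PLFA", normalize_fatty_acid("10Me16:0")): "actinomycetes",
    ("PLFA", normalize_fatty_acid("18:2w6.9")): "fungi",
    ("NLFA", normalize_fatty_acid("16:1w5")): "AMF",
}

POOLS = ("bacteria", "actinomycetes", "fungi", "AMF")


@dataclass
class BiomarkerMap:
    """Assignment of fatty-acid names (per assay) to microbial pools."""

    mapping: dict[tuple[str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKERS))

    def __post_init__(self) -> None:
        for (assay, fa), pool in self.mapping.items():
            if assay not in ("PLFA", "NLFA"):
                raise ValidationError(f"unknown assay {assay!r} for {fa!r}")
            if pool not in POOLS:
                raise ValidationError(f"unknown pool {pool!r} for {fa!r}")

    def pool_of(self, assay: str, fatty_acid: str) -> str | None:
        return self.mapping.get((assay, normalize_fatty_acid(fatty_acid)))

    def with_overrides(self, overrides: Mapping[tuple[str, str], str]) -> "BiomarkerMap":
        merged = dict(self.mapping)
        merged.update({(a, normalize_fatty_acid(f)): p
                       for (a, f), p in overrides.items()})
        return BiomarkerMap(mapping=merged)
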