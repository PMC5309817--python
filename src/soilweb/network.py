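"""Per-stage co-occurrence networks and network-tightening statistics.

A co-occurrence network for one successional stage is built from the
stage's samples only: taxa occurring in fewer than two samples of the stage
are dropped, pairwise Spearman rank correlations are computed over the
remaining taxa, and pairs with positive correlation above a threshold
(default 0.9) become edges. "Tightening" is quantified as connectance --
super-threshold correlations as a percentage of all counted taxon pairs --
plus group-level interaction strengths (the fraction of taxon pairs between
two functional groups that exceed the threshold).

Two denominator policies are supported, because "all possible connections"
can be read with or without within-group pairs:

- ``all_pairs``: every unordered pair of retained taxa, N(N-1)/2;
- ``between_only``: only pairs spanning two groups, sum over a<b of |a|*|b|.

Undefined correlations (a zero-variance rank vector, e.g. a taxon present
in every sample after binarisation) count in the denominator but can never
be edges, so the denominator depends only on which taxa were retained.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceTable, ValidationError

POLICIES = ("all_pairs", "between_only")


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rank-correlation matrix over taxa.

    Entries are in [-1, 1]; NaN marks an undefined correlation (at least
    one of the two rank vectors has zero variance). ``n_samples`` records
    how many samples the correlations were computed over.
    """

    rho: pd.DataFrame
    n_samples: int

    @property
    def taxa(self) -> list[str]:
        return list(self.rho.index)

    def defined(self) -> pd.DataFrame:
        return self.rho.notna()


@dataclass(frozen=True)
class Edge:
    taxon_a: str
    taxon_b: str
    rho: float


@dataclass
class EdgeSet:
    """Positive super-threshold correlation edges, canonically ordered a < b."""

    edges: list[Edge]
    tau: float
    strict: bool = True

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.taxon_a, e.taxon_b, e.rho) for e in self.edges],
            columns=["taxon_a", "taxon_b", "rho"],
        )


@dataclass
class NetworkSummary:
    """Connectance bookkeeping for one stage network."""

    stage: str
    n_strong: int
    n_possible: int
    policy: str
    tau: float

    @property
    def connectance_pct(self) -> float:
        return connectance(self.n_strong, self.n_possible)


@dataclass
class GroupInteraction:
    """Strength of association between two functional groups.

    ``interaction_strength`` is the number of super-threshold taxon pairs
    divided by all possible pairs between the two groups (|a| * |b| for
    distinct groups, C(n, 2) within a group). Within-group entries are
    computed but flagged ``displayed=False``, mirroring how such links are
    calculated but left out of network figures.
    """

    group_a: str
    group_b: str
    n_strong_ab: int
    n_possible_ab: int
    displayed: bool = True

    @property
    def interaction_strength(self) -> float:
        if self.n_possible_ab == 0:
            return 0.0
        return self.n_strong_ab / self.n_possible_ab


@dataclass
class StageNetworkResult:
    """Full network-analysis output for one successional stage."""

    stage: str
    correlation: CorrelationMatrix
    edge_set: EdgeSet
    summary: NetworkSummary
    subgroup_interactions: list[GroupInteraction]
    main_group_interactions: list[GroupInteraction]
    groups: pd.Series = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def filter_single_occurrence(table: AbundanceTable, stage: str) -> AbundanceTable:
    """Restrict to one stage's samples and drop taxa occurring in < 2 of them.

    Single-sample occurrences within a stage are removed before the
    correlation matrix is built; taxa absent from the stage entirely are
    removed too.
    """
    samples = table.samples_of_stage(stage)
    sub = table.values[samples]
    present = (sub > 0).sum(axis=1)
    keep = present[present >= 2].index
    return table.subset(taxa=list(keep), samples=samples)


def spearman_matrix(table: AbundanceTable | pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman rank correlation over taxa (rows), average ranks.

    Zero-variance vectors (constant across samples) yield NaN against every
    partner and on the diagonal: the correlation is undefined, and the
    marker never propagates into counts -- undefined pairs are simply
    non-edges.
    """
    values = table.values if isinstance(table, AbundanceTable) else table
    arr = np.asarray(values, dtype=float)
    n_taxa, n_samples = arr.shape
    if n_samples < 2:
        raise ValidationError("Spearman correlation needs at least 2 samples")
    if n_taxa < 2:
        raise ValidationError("Spearman correlation needs at least 2 taxa")
    # Spearman = Pearson on average ranks; done explicitly because the
    # one-shot scipy routine degenerates to a scalar on constant rows.
    ranks = stats.rankdata(arr, axis=1)
    constant = np.std(ranks, axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        rho = np.corrcoef(ranks)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    frame = pd.DataFrame(rho, index=values.index, columns=values.index)
    return CorrelationMatrix(rho=frame, n_samples=n_samples)


def build_edges(matrix: CorrelationMatrix, tau: float = 0.9,
                strict: bool = True) -> EdgeSet:
    """Keep positive correlations above the threshold as edges.

    ``strict`` selects rho > tau (the default) versus rho >= tau; with
    continuous abundances the two differ only at exact ties. Negative
    correlations never form edges, and undefined (NaN) pairs are non-edges.
    """
    if not 0.0 < tau < 1.0:
        raise ValidationError(f"threshold tau must be in (0, 1), got {tau}")
    taxa = matrix.taxa
    rho = matrix.rho.to_numpy()
    edges: list[Edge] = []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        r = rho[i, j]
        if np.isnan(r):
            continue
        if (r > tau) if strict else (r >= tau):
            a, b = sorted((taxa[i], taxa[j]))
            edges.append(Edge(a, b, float(r)))
    return EdgeSet(edges=edges, tau=tau, strict=strict)


def connectance(n_strong: int, n_possible: int) -> float:
    """Percentage connectance: 100 * strong correlations / possible pairs."""
    if n_possible <= 0:
        raise ValidationError("n_possible must be positive")
    if not 0 <= n_strong <= n_possible:
        raise ValidationError("need 0 <= n_strong <= n_possible")
    return 100.0 * n_strong / n_possible


def count_possible(group_sizes: Sequence[int] | Mapping[str, int],
                   policy: str = "all_pairs") -> int:
    """Number of counted taxon pairs under a denominator policy."""
    if isinstance(group_sizes, Mapping):
        sizes = list(group_sizes.values())
    else:
        sizes = list(group_sizes)
    if not sizes or any(s < 0 for s in sizes):
        raise ValidationError("group sizes must be a non-empty list of >= 0")
    if policy == "all_pairs":
        n = sum(sizes)
        return n * (n - 1) // 2
    if policy == "between_only":
        return sum(a * b for a, b in itertools.combinations(sizes, 2))
    raise ValidationError(f"unknown policy {policy!r}")


def interaction_strengths(edge_set: EdgeSet,
                          groups: Mapping[str, str] | pd.Series,
                          ) -> list[GroupInteraction]:
    """Group-level interaction strengths from a thresholded edge set.

    ``groups`` maps every retained taxon to its functional group; the group
    sizes define the possible-pair denominators. Every unordered group pair
    (including each group with itself) gets an entry; within-group entries
    are flagged ``displayed=False``.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    sizes = groups.value_counts().to_dict()
    strong: dict[tuple[str, str], int] = {}
    for e in edge_set.edges:
        for t in (e.taxon_a, e.taxon_b):
            if t not in groups.index:
                raise ValidationError(f"taxon {t!r} has no group assignment")
        pair = tuple(sorted((groups[e.taxon_a], groups[e.taxon_b])))
        strong[pair] = strong.get(pair, 0) + 1
    out: list[GroupInteraction] = []
    labels = sorted(sizes)
    for a, b in itertools.combinations_with_replacement(labels, 2):
        if a == b:
            possible = sizes[a] * (sizes[a] - 1) // 2
            displayed = False
        else:
            possible = sizes[a] * sizes[b]
            displayed = True
        out.append(GroupInteraction(
            group_a=a, group_b=b,
            n_strong_ab=strong.get((a, b), 0),
            n_possible_ab=possible,
            displayed=displayed,
        ))
    return out


def binarize(table: AbundanceTable) -> AbundanceTable:
    """Presence-absence transform: abundance > 0 becomes 1, else 0.

    The downstream pipeline is unchanged (Spearman on 0/1 vectors), which
    is the robustness check that co-occurrence patterns do not hinge on the
    abundance scale.
    """
    return AbundanceTable(
        values=(table.values > 0).astype(float),
        taxon_meta=table.taxon_meta,
        sample_meta=table.sample_meta,
    )


def shannon_index(abundances: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i over positive proportions."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any() or not np.all(np.isfinite(a)):
        raise ValidationError("abundances must be finite and non-negative")
    total = a.sum()
    if total <= 0:
        raise ValidationError("Shannon index of an all-zero vector is undefined")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def stage_network(table: AbundanceTable, stage: str, tau: float = 0.9,
                  policy: str = "all_pairs", strict: bool = True,
                  binary: bool = False,
                  summary_level: str = "subgroup") -> StageNetworkResult:
    """Run the full per-stage pipeline: filter, correlate, threshold, count."""
    if policy not in POLICIES:
        raise ValidationError(f"unknown policy {policy!r}")
    work = binarize(table) if binary else table
    retained = filter_single_occurrence(work, stage)
    matrix = spearman_matrix(retained)
    edge_set = build_edges(matrix, tau=tau, strict=strict)

    groups = retained.group_of(summary_level)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValidationError(f"taxa without {summary_level}: {missing}")
    sizes = groups.value_counts().to_dict()
    n_possible = count_possible(sizes, policy)
    if policy == "all_pairs":
        n_strong = len(edge_set)
    else:
        n_strong = sum(1 for e in edge_set.edges
                       if groups[e.taxon_a] != groups[e.taxon_b])
    summary = NetworkSummary(stage=stage, n_strong=n_strong,
                             n_possible=n_possible, policy=policy, tau=tau)
    return StageNetworkResult(
        stage=stage,
        correlation=matrix,
        edge_set=edge_set,
        summary=summary,
        subgroup_interactions=interaction_strengths(
            edge_set, retained.group_of("subgroup")),
        main_group_interactions=interaction_strengths(
            edge_set, retained.group_of("main_group")),
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

EDGE_FORMATS = ("SIF", "GraphML", "TSV")


def export_edges(result: StageNetworkResult, path: str | Path,
                 fmt: str = "TSV") -> None:
    """Write the thresholded edge list as SIF, GraphML, or TSV.

    SIF lines read ``a pp b``; GraphML carries the correlation as edge
    attribute ``rho`` and the functional group as node attribute ``group``;
    TSV has columns a, b, rho, group_a, group_b.
    """
    groups = result.groups
    if fmt == "SIF":
        with open(path, "w", encoding="utf-8") as fh:
            for e in result.edge_set.edges:
                fh.write(f"{e.taxon_a} pp {e.taxon_b}\n")
    elif fmt == "GraphML":
        g = nx.Graph()
        for taxon in result.correlation.taxa:
            g.add_node(taxon, group=str(groups.get(taxon, "")))
        for e in result.edge_set.edges:
            g.add_edge(e.taxon_a, e.taxon_b, rho=e.rho)
        nx.write_graphml(g, path)
    elif fmt == "TSV":
        rows = [{
            "a": e.taxon_a, "b": e.taxon_b, "rho": e.rho,
            "group_a": groups.get(e.taxon_a, ""),
            "group_b": groups.get(e.taxon_b, ""),
        } for e in result.edge_set.edges]
        pd.DataFrame(rows, columns=["a", "b", "rho", "group_a", "group_b"]) \
            .to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(
            f"unknown export format {fmt!r}; choose from {EDGE_FORMATS}")


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class CooccurrenceNetwork:
    """Co-occurrence network model over a successional abundance table.

    Parameters
    ----------
    table : AbundanceTable
        Taxa x samples abundances with stage annotations.
    tau : float
        Correlation threshold for a "strong" association (default 0.9).
    policy : str
        Denominator policy, ``all_pairs`` or ``between_only``.
    strict : bool
        Strong means rho > tau when True (default), rho >= tau otherwise.
    binary : bool
        Run on presence-absence data instead of abundances.
    summary_level : str
        Grouping level for the connectance denominator under
        ``between_only`` and for the summary table.
    """

    def __init__(self, table: AbundanceTable, tau: float = 0.9,
                 policy: str = "all_pairs", strict: bool = True,
                 binary: bool = False, summary_level: str = "subgroup"):
        if policy not in POLICIES:
            raise ValidationError(f"unknown policy {policy!r}")
        self.table = table
        self.tau = tau
        self.policy = policy
        self.strict = strict
        self.binary = binary
        self.summary_level = summary_level

    def fit(self, stages: Sequence[str] | None = None) -> "NetworkResults":
        """Build one network per stage and collect tightening statistics."""
        stages = list(stages) if stages is not None else self.table.stages
        results = {
            stage: stage_network(
                self.table, stage, tau=self.tau, policy=self.policy,
                strict=self.strict, binary=self.binary,
                summary_level=self.summary_level)
            for stage in stages
        }
        return NetworkResults(model=self, stage_results=results)


class NetworkResults:
    """Fitted per-stage networks with connectance and interaction strengths."""

    def __init__(self, model: CooccurrenceNetwork,
                 stage_results: dict[str, StageNetworkResult]):
        self.model = model
        self.stage_results = stage_results

    def __getitem__(self, stage: str) -> StageNetworkResult:
        return self.stage_results[stage]

    @property
    def connectance(self) -> pd.Series:
        return pd.Series({s: r.summary.connectance_pct
                          for s, r in self.stage_results.items()},
                         name="connectance_pct")

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for stage, r in self.stage_results.items():
            rows.append({
                "stage": stage,
                "n_taxa": len(r.correlation.taxa),
                "n_strong": r.summary.n_strong,
                "n_possible": r.summary.n_possible,
                "connectance_pct": r.summary.connectance_pct,
                "policy": r.summary.policy,
                "tau": r.summary.tau,
            })
        return pd.DataFrame(rows)

    def interaction_frame(self, level: str = "subgroup") -> pd.DataFrame:
        rows = []
        for stage, r in self.stage_results.items():
            interactions = (r.subgroup_interactions if level == "subgroup"
                            else r.main_group_interactions)
            for gi in interactions:
                rows.append({
                    "stage": stage, "group_a": gi.group_a, "group_b": gi.group_b,
                    "n_strong": gi.n_strong_ab, "n_possible": gi.n_possible_ab,
                    "interaction_strength": gi.interaction_strength,
                    "displayed": gi.displayed,
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame()
        lines = ["Co-occurrence network tightening summary",
                 f"threshold tau = {self.model.tau} "
                 f"({'strict' if self.model.strict else 'inclusive'}), "
                 f"policy = {self.model.policy}, "
                 f"{'presence-absence' if self.model.binary else 'abundance'} data",
                 df.to_string(index=False, float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)
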