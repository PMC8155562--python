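"""Quant-matrix normalization and correlation-clique protein summarization.

Quant matrices are pandas DataFrames (rows = features, columns = samples,
NaN = missing). The pipeline: scale each sample by its median intensity,
filter rows by missingness, roll peptides up to proteins by selecting the
largest subgroup of at least three peptides whose pairwise Spearman
correlations all reach the threshold (a maximum clique in the correlation
graph), summing those peptides' raw intensities, and finally
log2-transforming, mean-centering and SD-scaling each row.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class SummarizationConfig:
    """Correlation-clique rollup knobs.

    A protein is summarized from its largest subgroup of at least
    ``min_group`` peptides in which every pair has Spearman correlation of
    at least ``rho_min``; pairs are correlated on pairwise-complete samples
    and need at least ``min_overlap`` of them to form an edge. Clique
    search is exact up to ``exact_cap`` peptides, greedy beyond.
    """

    min_group: int = 3
    rho_min: float = 0.7
    min_overlap: int = 6
    exact_cap: int = 30
    fallback: str = "drop"  # or "sum-all"

    def __post_init__(self) -> None:
        if self.min_group < 2:
            raise QuantError("min_group must be >= 2")
        if not -1.0 < self.rho_min < 1.0:
            raise QuantError("rho_min must lie in (-1, 1)")
        if self.fallback not in ("drop", "sum-all"):
            raise QuantError("fallback must be 'drop' or 'sum-all'")


@dataclass
class ProteinSummary:
    protein_id: str
    member_peptides: list[str]
    summed: pd.Series  # raw summed intensity per sample
    scaled: pd.Series  # log2/centered/scaled version


@dataclass(frozen=True)
class CorrelationResult:
    feature_id: str
    rho: float
    pvalue: float
    n: int


def median_scale(m: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample (column) by its median over observed values."""
    if (m < 0).any().any():
        raise QuantError("raw quant matrix must be non-negative")
    medians = m.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise QuantError(f"columns with no observed values: {bad}")
    return m.div(medians, axis=1)


def log2_center_scale(m: pd.DataFrame) -> pd.DataFrame:
    """Per row over observed values: log2, subtract mean, divide by SD.

    Scaling uses the sample SD (ddof=1); rows with zero variance become
    centered zeros with a warning.
    """
    if (m <= 0).any().any():
        raise QuantError("log2 scaling requires strictly positive observed values")
    logged = np.log2(m)
    centered = logged.sub(logged.mean(axis=1, skipna=True), axis=0)
    sd = logged.std(axis=1, ddof=1, skipna=True)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant rows scaled to zeros", stacklevel=2
        )
        sd = sd.mask(flat, 1.0)
    return centered.div(sd, axis=0)


def filter_missingness(m: pd.DataFrame, max_frac: float = 0.30) -> pd.DataFrame:
    """Keep rows whose missing fraction is strictly below ``max_frac``."""
    frac = m.isna().mean(axis=1)
    return m.loc[frac < max_frac]


def _pairwise_spearman(a: pd.Series, b: pd.Series, min_overlap: int) -> float | None:
    both = a.notna() & b.notna()
    if both.sum() < min_overlap:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(a[both], b[both]).statistic
    return None if np.isnan(rho) else float(rho)


def _greedy_clique(graph: nx.Graph, weight: dict[str, float]) -> list[str]:
    """Degeneracy-ordered greedy clique, heaviest nodes first."""
    nodes = sorted(graph.nodes, key=lambda n: (-graph.degree(n), -weight[n], n))
    best: list[str] = []
    for seed in nodes:
        clique = [seed]
        for cand in nodes:
            if cand != seed and all(graph.has_edge(cand, c) for c in clique):
                clique.append(cand)
        if len(clique) > len(best):
            best = clique
    return best


def correlation_graph(
    peptides: pd.DataFrame, cfg: SummarizationConfig
) -> nx.Graph:
    """Graph over peptide rows: edge iff pairwise Spearman >= rho_min on at
    least ``min_overlap`` complete pairs."""
    g = nx.Graph()
    g.add_nodes_from(peptides.index)
    for a, b in itertools.combinations(peptides.index, 2):
        rho = _pairwise_spearman(peptides.loc[a], peptides.loc[b], cfg.min_overlap)
        if rho is not None and rho >= cfg.rho_min:
            g.add_edge(a, b)
    return g


def select_clique(
    peptides: pd.DataFrame, cfg: SummarizationConfig
) -> list[str] | None:
    """Largest qualifying peptide clique, or None.

    Exact maximal-clique enumeration up to ``exact_cap`` peptides; greedy
    degeneracy-ordered search beyond. Size ties break to the clique with
    the larger total raw intensity, then lexicographically, so selection is
    deterministic.
    """
    g = correlation_graph(peptides, cfg)
    totals = peptides.sum(axis=1, skipna=True).to_dict()
    if g.number_of_nodes() <= cfg.exact_cap:
        cliques = [sorted(c) for c in nx.find_cliques(g)]
    else:
        cliques = [sorted(_greedy_clique(g, totals))]
    cliques = [c for c in cliques if len(c) >= cfg.min_group]
    if not cliques:
        return None
    best_score = max((len(c), sum(totals[p] for p in c)) for c in cliques)
    tied = [c for c in cliques if (len(c), sum(totals[p] for p in c)) == best_score]
    return min(tied)  # lexicographic tie-break for determinism


def summarize_protein(
    protein_id: str,
    peptides: pd.DataFrame,
    cfg: SummarizationConfig = SummarizationConfig(),
) -> ProteinSummary | None:
    """Roll one protein's peptide rows up to a single intensity profile.

    Members of the selected clique are summed per sample over observed
    values (a sample where every member is missing stays missing), then the
    summed row is log2-transformed, centered and SD-scaled.
    """
    clique = select_clique(peptides, cfg)
    if clique is None:
        if cfg.fallback == "drop":
            return None
        clique = sorted(peptides.index)
    members = peptides.loc[clique]
    summed = members.sum(axis=0, skipna=True)
    summed[members.isna().all(axis=0)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled = log2_center_scale(summed.to_frame().T).iloc[0]
    return ProteinSummary(
        protein_id=protein_id,
        member_peptides=list(clique),
        summed=summed,
        scaled=scaled,
    )


def summarize_proteins(
    peptide_matrix: pd.DataFrame,
    peptide_to_protein: dict[str, str],
    cfg: SummarizationConfig = SummarizationConfig(),
) -> tuple[pd.DataFrame, dict[str, ProteinSummary]]:
    """Summarize every protein; returns (summed-intensity matrix, summaries)."""
    groups: dict[str, list[str]] = {}
    for pep in peptide_matrix.index:
        prot = peptide_to_protein.get(pep)
        if prot is not None:
            groups.setdefault(prot, []).append(pep)
    summaries: dict[str, ProteinSummary] = {}
    rows = {}
    for prot in sorted(groups):
        summary = summarize_protein(prot, peptide_matrix.loc[groups[prot]], cfg)
        if summary is not None:
            summaries[prot] = summary
            rows[prot] = summary.summed
    matrix = pd.DataFrame(rows).T
    matrix.index.name = "protein"
    return matrix, summaries


def spearman_pairs(
    x: pd.DataFrame,
    y: pd.DataFrame,
    pairing: dict[str, str],
    min_n: int = 3,
) -> list[CorrelationResult]:
    """Spearman correlation per paired row across shared samples.

    Ranks use the average-rank convention for ties; the p-value comes from
    the t approximation on rho with n - 2 degrees of freedom. Features with
    fewer than ``min_n`` complete pairs are skipped.
    """
    shared = [c for c in x.columns if c in set(y.columns)]
    if not shared:
        raise QuantError("x and y share no samples")
    out = []
    for xid, yid in pairing.items():
        if xid not in x.index or yid not in y.index:
            continue
        a, b = x.loc[xid, shared], y.loc[yid, shared]
        both = a.notna() & b.notna()
        n = int(both.sum())
        if n < min_n:
            continue
        av, bv = a[both].to_numpy(float), b[both].to_numpy(float)
        ra, rb = stats.rankdata(av), stats.rankdata(bv)
        if np.ptp(ra) == 0 or np.ptp(rb) == 0:
            continue
        rho = float(np.corrcoef(ra, rb)[0, 1])
        rho = float(np.clip(rho, -1.0, 1.0))
        if abs(rho) == 1.0 or n <= 2:
            p = 0.0 if n > 2 else 1.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        out.append(CorrelationResult(feature_id=xid, rho=rho, pvalue=p, n=n))
    return out
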