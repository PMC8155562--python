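"""Combining peptide results searched against multiple spectral libraries.

When the same DIA data are mined with several libraries (the study's own
plus external ones), each peptide group may be quantified in any subset of
them. Three precedence rules pick one record per peptide group:

1. quantified in the workflow's own library -> use that p-value;
2. quantified in exactly one library -> use that p-value;
3. quantified in two or more external libraries but not the own one ->
   use the record with the lower (minimum) p-value.

The combined table then gets Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CombineError(ValueError):
    pass


PeptideKey = tuple[str, int]  # (sequence, precursor charge)


@dataclass
class LibrarySearchResult:
    """Per-library peptide quantifications.

    ``rows`` maps (peptide, charge) to a record dict that must contain
    'pvalue' and may carry per-sample quantities.
    """

    library_id: str
    rows: dict[PeptideKey, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, rec in self.rows.items():
            p = rec.get("pvalue")
            if p is None or not 0.0 < p <= 1.0:
                raise CombineError(
                    f"library {self.library_id}: key {key} has invalid p-value {p!r}"
                )

    @classmethod
    def from_frame(cls, library_id: str, df: pd.DataFrame) -> "LibrarySearchResult":
        """Build from a tsv-shaped frame (peptide, charge, pvalue, samples...)."""
        required = {"peptide", "charge", "pvalue"}
        missing = required - set(df.columns)
        if missing:
            raise CombineError(f"library {library_id}: missing columns {sorted(missing)}")
        keys = list(zip(df["peptide"], df["charge"].astype(int)))
        if len(set(keys)) != len(keys):
            raise CombineError(f"library {library_id}: duplicate (peptide, charge) keys")
        sample_cols = [c for c in df.columns if c not in required]
        rows = {}
        for key, (_, r) in zip(keys, df.iterrows()):
            rows[key] = {
                "pvalue": float(r["pvalue"]),
                "quantities": {c: r[c] for c in sample_cols},
            }
        return cls(library_id, rows)


def combine_results(
    results: list[LibrarySearchResult], own_id: str
) -> pd.DataFrame:
    """Merge per-library results into one row per peptide group.

    Returns a frame indexed by (peptide, charge) with columns ``pvalue``,
    ``source`` (winning library id) and the winning record's quantities.
    The q-value column is added separately by :func:`bh_qvalues`.
    """
    ids = [r.library_id for r in results]
    if len(set(ids)) != len(ids):
        raise CombineError("duplicate library ids")
    if own_id not in ids:
        raise CombineError(f"own library {own_id!r} not among {ids}")
    own = next(r for r in results if r.library_id == own_id)
    externals = [r for r in results if r.library_id != own_id]

    all_keys: set[PeptideKey] = set()
    for r in results:
        all_keys.update(r.rows)

    records = []
    for key in sorted(all_keys):
        if key in own.rows:
            src, rec = own_id, own.rows[key]
        else:
            holders = [(r.library_id, r.rows[key]) for r in externals if key in r.rows]
            # unique holder or minimum-p external; id breaks exact p ties
            src, rec = min(holders, key=lambda h: (h[1]["pvalue"], h[0]))
        row = {"peptide": key[0], "charge": key[1], "pvalue": rec["pvalue"], "source": src}
        row.update(rec.get("quantities", {}))
        records.append(row)
    return pd.DataFrame.from_records(records).set_index(["peptide", "charge"])


def bh_qvalues(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_i = min over j with p_j >= p_i of (p_j * m / rank_j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise CombineError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def combine_and_score(
    results: list[LibrarySearchResult], own_id: str
) -> pd.DataFrame:
    """Convenience: combine, then append a ``qvalue`` column."""
    table = combine_results(results, own_id)
    table["qvalue"] = bh_qvalues(table["pvalue"].to_numpy())
    return table
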