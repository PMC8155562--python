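"""RNA-guided peptide libraries: SAAV-specific and isoform-combination.

Single-amino-acid variants (SAAVs) called from RNA-seq are applied to
their reference proteins; in-silico digestion of reference and variant
sequences yields the peptides that arise only from the variant — typically
one, more when the substitution creates or destroys a tryptic cleavage
site. Those identifying peptides are concatenated into one FASTA record
per SAAV. For isoform-aware searching, every protein isoform of a gene is
digested and each peptide (of at least five residues) is mapped to the
exact set of isoforms containing it; peptides sharing an isoform set are
concatenated into a mock protein specific to that combination.

Both FASTA outputs ship with a sidecar table of member peptides and their
coordinates within the concatenated record, so downstream transition
building works from real peptides and never from concatenation junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from dialib import chem


class ProteogenomicsError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    """One protein-level consequence of a nonsynonymous SNV."""

    protein_id: str
    position: int  # 1-based
    ref: str
    alt: str
    alt_reads: int
    coverage: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ProteogenomicsError("position must be >= 1")
        if self.ref == self.alt:
            raise ProteogenomicsError("reference and alternate residues are equal")
        if self.alt_reads < 0 or self.coverage < self.alt_reads:
            raise ProteogenomicsError("read counts inconsistent")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.protein_id}:{self.ref}{self.position}{self.alt}"
            )


@dataclass
class SaavPeptideSet:
    """Peptides that arise only from the variant protein, in positional order."""

    variant: VariantCall
    peptides: list[chem.PeptideSeq] = field(default_factory=list)

    @property
    def label(self) -> str:
        return self.variant.label


@dataclass(frozen=True)
class IsoformRecord:
    gene_id: str
    transcript_id: str
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not (self.gene_id and self.transcript_id and self.protein_id):
            raise ProteogenomicsError("isoform ids must be nonempty")
        if not self.sequence:
            raise ProteogenomicsError("isoform sequence must be nonempty")


@dataclass
class IsoformGroup:
    """All retained peptides mapping to exactly this set of isoforms."""

    isoform_ids: frozenset[str]
    peptides: list[str]

    @property
    def mock_id(self) -> str:
        return "ISOGRP|" + "+".join(sorted(self.isoform_ids))

    @property
    def mock_sequence(self) -> str:
        return "".join(self.peptides)


def filter_variants(
    calls: list[VariantCall], min_alt: int = 2, min_cov: int = 10
) -> list[VariantCall]:
    """Keep calls with at least ``min_alt`` supporting reads and at least
    ``min_cov`` total coverage (both inclusive)."""
    return [c for c in calls if c.alt_reads >= min_alt and c.coverage >= min_cov]


def apply_variant(sequence: str, call: VariantCall) -> str:
    """Substitute one residue; the reference residue must match."""
    if not 1 <= call.position <= len(sequence):
        raise ProteogenomicsError(
            f"position {call.position} outside protein of length {len(sequence)}"
        )
    found = sequence[call.position - 1]
    if found != call.ref:
        raise ProteogenomicsError(
            f"reference mismatch at position {call.position}: "
            f"expected {call.ref}, found {found}"
        )
    return sequence[: call.position - 1] + call.alt + sequence[call.position :]


def saav_specific_peptides(
    reference: str,
    call: VariantCall,
    rule: chem.CleavageRule | None = None,
    equate_il: bool = False,
) -> SaavPeptideSet:
    """Digest reference and variant; return variant peptides absent from
    the reference digest.

    Comparison is exact string equality, or I/L-collapsed when
    ``equate_il`` is set. The result may be empty (e.g., when every
    variant peptide falls outside the digestion length bounds); callers
    should record but not emit empty sets.
    """
    if rule is None:
        rule = chem.trypsin()
    variant_seq = apply_variant(reference, call)
    norm = chem.equate_il if equate_il else (lambda s: s)
    ref_peptides = {norm(p.sequence) for p in chem.digest(reference, rule)}
    specific = [
        p
        for p in chem.digest(variant_seq, rule, protein_id=call.protein_id)
        if norm(p.sequence) not in ref_peptides
    ]
    specific.sort(key=lambda p: p.start or 0)
    return SaavPeptideSet(variant=call, peptides=specific)


def build_saav_fasta(
    sets: list[SaavPeptideSet],
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """One concatenated record per SAAV plus a sidecar of member peptides.

    Headers are ``SAAV|<protein id>|<label>``; the sidecar gives each
    member peptide's 1-based coordinates within the concatenated sequence.
    Empty sets are skipped (nothing identifies those SAAVs).
    """
    records: list[tuple[str, str]] = []
    side_rows = []
    for s in sets:
        if not s.peptides:
            continue
        header = f"SAAV|{s.variant.protein_id}|{s.label}"
        seq = "".join(p.sequence for p in s.peptides)
        records.append((header, seq))
        pos = 1
        for p in s.peptides:
            side_rows.append(
                {
                    "record_id": header,
                    "peptide": p.sequence,
                    "start": pos,
                    "end": pos + len(p.sequence) - 1,
                }
            )
            pos += len(p.sequence)
    sidecar = pd.DataFrame(side_rows, columns=["record_id", "peptide", "start", "end"])
    return records, sidecar


def build_isoform_library(
    isoforms: list[IsoformRecord],
    rule: chem.CleavageRule | None = None,
    min_len: int = 5,
) -> tuple[list[IsoformGroup], list[tuple[str, str]], pd.DataFrame]:
    """Group digest peptides by the exact isoform set containing them.

    Every isoform is digested; distinct peptides of at least ``min_len``
    residues are keyed by the frozenset of isoform protein ids whose digest
    contains them; each key becomes one mock protein. Peptide order within
    a mock record follows position in the lexicographically smallest
    member isoform, making output deterministic. Returns (groups, FASTA
    records, sidecar frame).
    """
    if rule is None:
        rule = chem.trypsin(min_len=1, max_len=10**9)
    ids = [iso.protein_id for iso in isoforms]
    if len(set(ids)) != len(ids):
        raise ProteogenomicsError("duplicate isoform protein ids")

    peptide_sets: dict[str, set[str]] = {}
    positions: dict[tuple[str, str], int] = {}  # (protein, peptide) -> start
    for iso in isoforms:
        for p in chem.digest(iso.sequence, rule, protein_id=iso.protein_id):
            if len(p.sequence) < min_len:
                continue
            peptide_sets.setdefault(p.sequence, set()).add(iso.protein_id)
            key = (iso.protein_id, p.sequence)
            if key not in positions or (p.start or 0) < positions[key]:
                positions[key] = p.start or 0

    grouped: dict[frozenset[str], list[str]] = {}
    for pep, iso_ids in peptide_sets.items():
        grouped.setdefault(frozenset(iso_ids), []).append(pep)

    groups = []
    for iso_set in sorted(grouped, key=lambda s: sorted(s)):
        anchor = min(iso_set)
        peps = sorted(grouped[iso_set], key=lambda p: (positions[(anchor, p)], p))
        groups.append(IsoformGroup(isoform_ids=iso_set, peptides=peps))

    records = [(g.mock_id, g.mock_sequence) for g in groups]
    side_rows = []
    for g in groups:
        pos = 1
        for pep in g.peptides:
            side_rows.append(
                {
                    "record_id": g.mock_id,
                    "peptide": pep,
                    "start": pos,
                    "end": pos + len(pep) - 1,
                }
            )
            pos += len(pep)
    sidecar = pd.DataFrame(side_rows, columns=["record_id", "peptide", "start", "end"])
    return groups, records, sidecar


def read_variant_table(df: pd.DataFrame) -> list[VariantCall]:
    """Variant tsv columns: protein_id, pos, ref, alt, alt_reads, coverage
    and optional label."""
    required = {"protein_id", "pos", "ref", "alt", "alt_reads", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ProteogenomicsError(f"variant table missing columns {sorted(missing)}")
    calls = []
    for _, r in df.iterrows():
        label = r.get("label", "")
        if pd.isna(label):
            label = ""
        calls.append(
            VariantCall(
                protein_id=str(r["protein_id"]),
                position=int(r["pos"]),
                ref=str(r["ref"]),
                alt=str(r["alt"]),
                alt_reads=int(r["alt_reads"]),
                coverage=int(r["coverage"]),
                label=str(label or ""),
            )
        )
    return calls
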