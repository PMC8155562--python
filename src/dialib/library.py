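"""Consensus spectra, best-PSM selection, and y/b transition extraction.

The end product is an OpenSWATH-compatible generic transition list (GTL):
one row per precursor->fragment pair with library intensity and a
normalized retention time. Clustering of replicate DDA spectra happens
upstream; this module consumes spectrum->cluster assignments, merges each
cluster into a consensus spectrum, picks the best-scoring peptide-spectrum
match (PSM) per peptide group at a q-value ceiling, and matches consensus
peaks to theoretical y/b ion m/z within a ppm tolerance.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from dialib import chem
from dialib.io import read_gtl, write_gtl  # noqa: F401  (re-exported)


class LibraryError(ValueError):
    pass


@dataclass
class Spectrum:
    """One MS2 spectrum; peaks stored as parallel sorted arrays."""

    id: str
    precursor_mz: float
    precursor_charge: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise LibraryError("m/z and intensity arrays differ in length")
        if np.any(~np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise LibraryError("intensities must be finite and >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class ConsensusSpectrum:
    cluster_id: str
    member_count: int
    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.member_count < 1:
            raise LibraryError("consensus must have >= 1 member")


@dataclass(frozen=True)
class PSMRecord:
    """A scored peptide-spectrum match targeting a spectrum or cluster id."""

    target_id: str
    peptide: str
    precursor_charge: int
    score: float
    pvalue: float
    qvalue: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pvalue <= 1.0:
            raise LibraryError(f"p-value {self.pvalue} outside (0, 1]")
        if not 0.0 <= self.qvalue <= 1.0:
            raise LibraryError(f"q-value {self.qvalue} outside [0, 1]")


@dataclass(frozen=True)
class Transition:
    """One fragment-ion assay: the GTL row.

    ``product_mz`` is the theoretical fragment m/z; the matched experimental
    peak's position is kept in ``observed_mz`` for diagnostics but is not a
    GTL column.
    """

    group_id: str
    peptide: str
    precursor_charge: int
    precursor_mz: float
    product_mz: float
    series: str
    ordinal: int
    fragment_charge: int
    library_intensity: float
    normalized_rt: float
    protein_name: str = "unknown"
    decoy: bool = False
    full_peptide_name: str = ""
    observed_mz: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.library_intensity <= 0:
            raise LibraryError("library intensity must be positive")
        if not self.full_peptide_name:
            object.__setattr__(self, "full_peptide_name", self.peptide)


@dataclass(frozen=True)
class TransitionConfig:
    """Knobs for consensus building and transition extraction."""

    ppm_tolerance: float = 1.0
    series: tuple[str, ...] = ("y", "b")
    fragment_charges: tuple[int, ...] = (1, 2)
    q_ceiling: float = 0.10
    merge_tolerance_da: float = 0.02
    top_n: int | None = None  # keep all matched transitions by default

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise LibraryError("ppm tolerance must be positive")
        if not 0.0 < self.q_ceiling <= 1.0:
            raise LibraryError("q ceiling must be in (0, 1]")


def _merge_peaks(
    mz: np.ndarray, intensity: np.ndarray, tol: float, n_members: int
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy left-to-right merge of sorted peaks within ``tol`` Da.

    Merged m/z is the intensity-weighted mean; merged intensity is the
    summed intensity divided by the number of member spectra, so a peak
    present in every member keeps its average height.
    """
    out_mz: list[float] = []
    out_int: list[float] = []
    i = 0
    n = len(mz)
    while i < n:
        j = i + 1
        wsum = mz[i] * intensity[i]
        isum = intensity[i]
        centre = mz[i] if isum == 0 else wsum / isum
        while j < n and mz[j] - centre <= tol:
            wsum += mz[j] * intensity[j]
            isum += intensity[j]
            centre = wsum / isum if isum > 0 else mz[j]
            j += 1
        out_mz.append(centre if isum > 0 else float(np.mean(mz[i:j])))
        out_int.append(isum / n_members)
        i = j
    return np.asarray(out_mz), np.asarray(out_int)


def build_consensus(
    spectra: list[Spectrum],
    assignment: dict[str, str],
    cfg: TransitionConfig = TransitionConfig(),
) -> list[ConsensusSpectrum]:
    """Merge clustered spectra into one consensus spectrum per cluster.

    Peaks from all members within the merge tolerance collapse to a single
    peak; representative RT is the median member RT. Singleton clusters
    pass through unchanged.
    """
    by_id = {s.id: s for s in spectra}
    unknown = [sid for sid in assignment if sid not in by_id]
    if unknown:
        raise LibraryError(f"assignment references unknown spectra: {unknown[:5]}")
    clusters: dict[str, list[Spectrum]] = {}
    for sid, cid in assignment.items():
        clusters.setdefault(cid, []).append(by_id[sid])

    out = []
    for cid in sorted(clusters):
        members = sorted(clusters[cid], key=lambda s: s.id)
        if len(members) == 1:
            s = members[0]
            out.append(
                ConsensusSpectrum(cid, 1, s.precursor_mz, s.rt, s.mz.copy(), s.intensity.copy())
            )
            continue
        all_mz = np.concatenate([s.mz for s in members])
        all_int = np.concatenate([s.intensity for s in members])
        order = np.argsort(all_mz, kind="stable")
        mz, inten = _merge_peaks(
            all_mz[order], all_int[order], cfg.merge_tolerance_da, len(members)
        )
        out.append(
            ConsensusSpectrum(
                cluster_id=cid,
                member_count=len(members),
                precursor_mz=float(np.median([s.precursor_mz for s in members])),
                rt=float(statistics.median(s.rt for s in members)),
                mz=mz,
                intensity=inten,
            )
        )
    return out


def select_best_psms(
    psms: list[PSMRecord], cfg: TransitionConfig = TransitionConfig()
) -> dict[tuple[str, int], PSMRecord]:
    """Best PSM per peptide group (sequence + charge) under the q ceiling.

    Each group keeps its minimum-q PSM; ties break to the higher search
    score, then the lexicographically smallest target id, so output is
    deterministic. Groups whose best q-value is not below the ceiling are
    dropped.
    """
    best: dict[tuple[str, int], PSMRecord] = {}
    for psm in psms:
        key = (psm.peptide, psm.precursor_charge)
        cur = best.get(key)
        if cur is None or (psm.qvalue, -psm.score, psm.target_id) < (
            cur.qvalue,
            -cur.score,
            cur.target_id,
        ):
            best[key] = psm
    return {k: v for k, v in best.items() if v.qvalue < cfg.q_ceiling}


def extract_transitions(
    cs: ConsensusSpectrum,
    psm: PSMRecord,
    cfg: TransitionConfig = TransitionConfig(),
    protein_name: str = "unknown",
    table: chem.ResidueMassTable = chem.DEFAULT_TABLE,
) -> list[Transition]:
    """Match consensus peaks to theoretical y/b ions within the ppm window.

    For every theoretical fragment (all ordinals, configured series and
    charges), the closest observed peak within the tolerance is matched
    (ties break to the higher-intensity peak) and emitted as one transition
    carrying that peak's intensity; the normalized RT is the consensus RT.
    """
    if psm.target_id != cs.cluster_id:
        raise LibraryError(
            f"PSM targets {psm.target_id!r} but consensus is {cs.cluster_id!r}"
        )
    prec_mz = chem.precursor_mz(psm.peptide, psm.precursor_charge, table)
    group_id = f"{psm.peptide}/{psm.precursor_charge}"
    out = []
    for ion in chem.theoretical_fragments(
        psm.peptide, cfg.series, cfg.fragment_charges, table
    ):
        tol = ion.mz * cfg.ppm_tolerance * 1e-6
        lo = np.searchsorted(cs.mz, ion.mz - tol, side="left")
        hi = np.searchsorted(cs.mz, ion.mz + tol, side="right")
        if lo == hi:
            continue
        window = slice(lo, hi)
        dist = np.abs(cs.mz[window] - ion.mz)
        # closest peak wins; tie -> higher intensity
        best_local = min(
            range(hi - lo), key=lambda j: (dist[j], -cs.intensity[window][j])
        )
        idx = lo + best_local
        if cs.intensity[idx] <= 0:
            continue
        out.append(
            Transition(
                group_id=group_id,
                peptide=psm.peptide,
                precursor_charge=psm.precursor_charge,
                precursor_mz=prec_mz,
                product_mz=ion.mz,
                series=ion.series,
                ordinal=ion.ordinal,
                fragment_charge=ion.charge,
                library_intensity=float(cs.intensity[idx]),
                normalized_rt=cs.rt,
                protein_name=protein_name,
                observed_mz=float(cs.mz[idx]),
            )
        )
    if cfg.top_n is not None and len(out) > cfg.top_n:
        out = sorted(out, key=lambda t: -t.library_intensity)[: cfg.top_n]
        out.sort(key=lambda t: (t.series, t.ordinal, t.fragment_charge))
    return out


def build_library(
    spectra: list[Spectrum],
    assignment: dict[str, str],
    psms: list[PSMRecord],
    cfg: TransitionConfig = TransitionConfig(),
    protein_names: dict[str, str] | None = None,
) -> list[Transition]:
    """Full MakeGTL-style pass: consensus -> best PSMs -> transitions.

    ``protein_names`` maps peptide sequence -> protein id for the GTL
    ProteinName column.
    """
    consensus = {cs.cluster_id: cs for cs in build_consensus(spectra, assignment, cfg)}
    best = select_best_psms(psms, cfg)
    transitions: list[Transition] = []
    for (peptide, _charge), psm in sorted(best.items()):
        cs = consensus.get(psm.target_id)
        if cs is None:
            continue
        name = (protein_names or {}).get(peptide, "unknown")
        transitions.extend(extract_transitions(cs, psm, cfg, protein_name=name))
    return transitions
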