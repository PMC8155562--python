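"""Seeded generators for every input the workflows consume.

Each generator is a pure function of its configuration and seed and
returns ground truth alongside the synthetic files, so downstream modules
can be scored without re-deriving anything: proteome FASTA with digestible
tryptic composition, clustered MS2 spectra with known fragment and noise
peaks, per-run feature tables with known RT drift and known filter
violations, quant matrices with known protein abundances and decoy
peptides, and variant tables with known cleavage-site effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dialib import chem
from dialib.library import PSMRecord, Spectrum
from dialib.proteogenomics import VariantCall

RESIDUES = np.array(list(chem.STANDARD_RESIDUES))

# Tryptic-friendly composition: K/R at ~11% combined gives mean peptide
# length near 9; proline kept rare so cut suppression stays occasional.
_WEIGHTS = {"K": 0.055, "R": 0.055, "P": 0.02}
_BASE = (1.0 - sum(_WEIGHTS.values())) / (len(chem.STANDARD_RESIDUES) - len(_WEIGHTS))
RESIDUE_PROBS = np.array([_WEIGHTS.get(aa, _BASE) for aa in chem.STANDARD_RESIDUES])


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Proteome


def gen_proteome(
    n_proteins: int = 50,
    min_len: int = 80,
    max_len: int = 300,
    seed=0,
) -> list[tuple[str, str]]:
    """Random protein sequences whose tryptic digest (min length 5) is
    nonempty; deterministic under a fixed seed."""
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = _rng(seed)
    rule = chem.trypsin()
    records = []
    i = 0
    while len(records) < n_proteins:
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(RESIDUES, size=length, p=RESIDUE_PROBS))
        if not chem.digest(seq, rule):
            continue  # resample the rare digest-empty draw
        records.append((f"PROT{i:04d}", seq))
        i += 1
    return records


# ---------------------------------------------------------------------------
# Clustered spectra + PSMs (library-build scenario)


@dataclass
class SpectraTruth:
    """Per-peptide fragment annotations and per-spectrum peak provenance."""

    fragments: dict[str, list[chem.FragmentIon]] = field(default_factory=dict)
    fragment_mz: dict[str, set[float]] = field(default_factory=dict)
    noise_mz: dict[str, set[float]] = field(default_factory=dict)
    cluster_of: dict[str, str] = field(default_factory=dict)


def gen_spectra(
    peptides: list[str],
    seed=0,
    replicates: int = 3,
    jitter_ppm_sd: float = 0.3,
    noise_fraction: float = 0.2,
    precursor_charge: int = 2,
    fragment_charges: tuple[int, ...] = (1, 2),
    decoy_fraction: float = 0.1,
    gradient: tuple[float, float] = (0.0, 7200.0),
) -> tuple[list[Spectrum], dict[str, str], list[PSMRecord], SpectraTruth]:
    """Replicate MS2 spectra per peptide with known fragments and noise.

    Every spectrum contains all theoretical y/b peaks perturbed by Gaussian
    ppm jitter plus ``noise_fraction`` x (fragment count) uniform noise
    peaks. Replicates of one peptide share a cluster. True PSMs get
    q-values below 0.10; a ``decoy_fraction`` of extra shuffled-sequence
    PSMs get q-values above it.
    """
    rng = _rng(seed)
    spectra: list[Spectrum] = []
    assignment: dict[str, str] = {}
    psms: list[PSMRecord] = []
    truth = SpectraTruth()

    for i, pep in enumerate(peptides):
        cluster = f"clu{i:05d}"
        ions = chem.theoretical_fragments(pep, charges=fragment_charges)
        truth.fragments[pep] = ions
        theo = np.array([ion.mz for ion in ions])
        rt = float(rng.uniform(*gradient))
        n_noise = int(round(noise_fraction * len(ions)))
        for r in range(replicates):
            sid = f"spec{i:05d}_{r}"
            frag_mz = theo * (1.0 + rng.normal(0.0, jitter_ppm_sd, theo.size) * 1e-6)
            frag_int = rng.lognormal(mean=9.0, sigma=1.0, size=theo.size)
            noise_mz = rng.uniform(100.0, theo.max() + 100.0, size=n_noise)
            noise_int = rng.lognormal(mean=8.0, sigma=1.0, size=n_noise)
            spectra.append(
                Spectrum(
                    id=sid,
                    precursor_mz=chem.precursor_mz(pep, precursor_charge),
                    precursor_charge=precursor_charge,
                    rt=rt + float(rng.normal(0.0, 2.0)),
                    mz=np.concatenate([frag_mz, noise_mz]),
                    intensity=np.concatenate([frag_int, noise_int]),
                )
            )
            assignment[sid] = cluster
            truth.fragment_mz[sid] = set(frag_mz.tolist())
            truth.noise_mz[sid] = set(noise_mz.tolist())
            truth.cluster_of[sid] = cluster
        psms.append(
            PSMRecord(
                target_id=cluster,
                peptide=pep,
                precursor_charge=precursor_charge,
                score=float(rng.normal(5.0, 1.0)),
                pvalue=float(rng.uniform(1e-8, 1e-3)),
                qvalue=float(rng.uniform(0.001, 0.09)),
            )
        )
        if rng.uniform() < decoy_fraction:
            shuffled = "".join(rng.permutation(list(pep)))
            psms.append(
                PSMRecord(
                    target_id=cluster,
                    peptide=shuffled,
                    precursor_charge=precursor_charge,
                    score=float(rng.normal(1.0, 1.0)),
                    pvalue=float(rng.uniform(0.2, 1.0)),
                    qvalue=float(rng.uniform(0.10, 1.0)),
                )
            )
    return spectra, assignment, psms, truth


# ---------------------------------------------------------------------------
# RT feature tables (calibration scenario)


def gen_rt_runs(
    peptides: list[str],
    seed=0,
    n_runs: int = 30,
    gradient: tuple[float, float] = (0.0, 7200.0),
    slope: float = 1.05,
    intercept: float = 180.0,
    noise_sd: float = 6.0,
    frac_wide: float = 0.10,
    frac_dim: float = 0.10,
    frac_far: float = 0.05,
    frac_sparse: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-run feature observations under a known affine RT drift.

    Each peptide is assigned one violation class (good / wide / dim / far /
    sparse) so that configurable fractions fail exactly one anchor filter.
    Returns (feature table, per-peptide truth with class flags and drift
    parameters).
    """
    lo, hi = gradient
    if hi <= lo:
        raise ValueError("gradient span must be positive")
    rng = _rng(seed)
    n = len(peptides)
    lib_rt = rng.uniform(lo, hi, size=n)
    classes = rng.choice(
        ["good", "wide", "dim", "far", "sparse"],
        size=n,
        p=[1 - frac_wide - frac_dim - frac_far - frac_sparse,
           frac_wide, frac_dim, frac_far, frac_sparse],
    )
    rows = []
    truth_rows = []
    for i, pep in enumerate(peptides):
        cls = classes[i]
        runs = list(range(n_runs))
        if cls == "sparse":
            k = int(rng.integers(1, 20))
            runs = sorted(rng.choice(n_runs, size=min(k, n_runs), replace=False))
        for r in runs:
            obs = slope * lib_rt[i] + intercept + rng.normal(0.0, noise_sd)
            if cls == "far":
                obs += float(rng.choice([-1, 1])) * rng.uniform(700.0, 1500.0)
            width = (
                float(rng.uniform(16.5, 30.0))
                if cls == "wide"
                else float(np.clip(rng.normal(10.0, 2.0), 2.0, 16.4))
            )
            intensity = (
                float(10 ** rng.uniform(3.0, 4.99))
                if cls == "dim"
                else float(10 ** rng.uniform(5.0, 8.0))
            )
            rows.append(
                {
                    "peptide": pep,
                    "run": f"run{r:03d}",
                    "rt_obs": obs,
                    "rt_lib": lib_rt[i],
                    "width": width,
                    "intensity": intensity,
                }
            )
        truth_rows.append(
            {
                "peptide": pep,
                "class": cls,
                "rt_lib": lib_rt[i],
                "slope": slope,
                "intercept": intercept,
                "n_runs": len(runs),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Quant matrices (summarization / correlation scenario)


@dataclass
class QuantTruth:
    protein_log2: pd.DataFrame  # proteins x samples, true log2 abundance
    peptide_to_protein: dict[str, str]
    decoy_peptides: set[str]
    decoupled_transcripts: set[str]
    transcript_of: dict[str, str]  # protein -> transcript id


def gen_quant_dataset(
    seed=0,
    n_proteins: int = 100,
    n_true_peptides: int = 5,
    n_decoy_peptides: int = 2,
    n_samples: int = 30,
    peptide_sd: float = 0.2,
    sample_sd: float = 1.0,
    transcript_sd: float = 0.5,
    decoupled_fraction: float = 0.0,
    missing_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, QuantTruth]:
    """Peptide and transcript quant matrices with known protein abundance.

    Protein abundance is log-normal (base log2 level ~ N(20, 2), per-sample
    biological variation N(0, ``sample_sd``)). True peptides follow their
    protein plus N(0, ``peptide_sd``) on the log2 scale and a per-peptide
    ionization offset; decoy peptides are independent. Transcripts follow
    their protein (sd ``transcript_sd``) except for a ``decoupled_fraction``
    simulated independently. Missingness, if requested, censors the lowest
    ``missing_fraction`` quantile of peptide intensities (missing not at
    random, as in MS data).
    """
    rng = _rng(seed)
    samples = [f"S{j:02d}" for j in range(n_samples)]
    proteins = [f"P{i:03d}" for i in range(n_proteins)]

    base = rng.normal(20.0, 2.0, size=n_proteins)
    prot_log2 = base[:, None] + rng.normal(0.0, sample_sd, size=(n_proteins, n_samples))
    prot_df = pd.DataFrame(prot_log2, index=proteins, columns=samples)

    pep_rows = {}
    pep2prot: dict[str, str] = {}
    decoys: set[str] = set()
    for i, prot in enumerate(proteins):
        for j in range(n_true_peptides):
            pep = f"{prot}_pep{j}"
            offset = rng.normal(0.0, 1.0)
            pep_rows[pep] = prot_log2[i] + offset + rng.normal(
                0.0, peptide_sd, size=n_samples
            )
            pep2prot[pep] = prot
        for j in range(n_decoy_peptides):
            pep = f"{prot}_dec{j}"
            pep_rows[pep] = rng.normal(20.0, 2.0) + rng.normal(
                0.0, sample_sd, size=n_samples
            )
            pep2prot[pep] = prot
            decoys.add(pep)
    pep_log2 = pd.DataFrame.from_dict(pep_rows, orient="index", columns=samples)
    peptide_matrix = (2.0**pep_log2).astype(float)

    if missing_fraction > 0:
        cutoff = np.nanquantile(peptide_matrix.to_numpy(), missing_fraction)
        peptide_matrix = peptide_matrix.mask(peptide_matrix < cutoff)

    transcripts = {}
    transcript_of = {}
    decoupled: set[str] = set()
    for i, prot in enumerate(proteins):
        tid = f"T{i:03d}"
        transcript_of[prot] = tid
        if rng.uniform() < decoupled_fraction:
            transcripts[tid] = rng.normal(10.0, 2.0) + rng.normal(
                0.0, sample_sd, size=n_samples
            )
            decoupled.add(tid)
        else:
            transcripts[tid] = prot_log2[i] + rng.normal(
                0.0, transcript_sd, size=n_samples
            )
    transcript_matrix = (
        2.0 ** pd.DataFrame.from_dict(transcripts, orient="index", columns=samples)
    ).astype(float)

    truth = QuantTruth(
        protein_log2=prot_df,
        peptide_to_protein=pep2prot,
        decoy_peptides=decoys,
        decoupled_transcripts=decoupled,
        transcript_of=transcript_of,
    )
    return peptide_matrix, transcript_matrix, truth


# ---------------------------------------------------------------------------
# Variants (SAAV scenario)


def gen_variants(
    proteome: list[tuple[str, str]],
    seed=0,
    n_variants: int = 20,
    site_altering_fraction: float = 0.3,
    fail_filter_fraction: float = 0.2,
) -> tuple[list[VariantCall], pd.DataFrame]:
    """Random single-residue variants over a proteome with known effects.

    A ``site_altering_fraction`` of variants create or destroy a tryptic
    cleavage site (alt or ref is K/R); a ``fail_filter_fraction`` get read
    counts below the alt-read or coverage thresholds. Returns the calls and
    a truth frame with the intended effect class per call.
    """
    rng = _rng(seed)
    calls = []
    truth_rows = []
    attempts = 0
    while len(calls) < n_variants and attempts < n_variants * 200:
        attempts += 1
        pid, seq = proteome[int(rng.integers(len(proteome)))]
        pos = int(rng.integers(2, len(seq)))  # 1-based, avoid terminal residue
        ref = seq[pos - 1]
        if seq[pos] == "P":  # keep cut-site semantics unambiguous
            continue
        effect = "neutral"
        if rng.uniform() < site_altering_fraction:
            if ref in "KR":
                alt = "A"
                effect = "site_destroying"
            else:
                # a created cut site must leave >=3 residues to the nearest
                # cut on both sides, so neither new fragment collides with a
                # short pre-existing reference peptide
                left = seq[max(0, pos - 4) : pos - 1]
                right = seq[pos : pos + 3]
                if (
                    len(left) < 3 or len(right) < 3
                    or set(left + right) & set("KR")
                    or pos + 3 > len(seq)
                ):
                    continue
                alt = "K"
                effect = "site_creating"
        else:
            if ref in "KRP":
                continue
            choices = [aa for aa in chem.STANDARD_RESIDUES if aa not in ("K", "R", "P", ref)]
            alt = str(rng.choice(choices))
        fails = rng.uniform() < fail_filter_fraction
        if fails:
            if rng.uniform() < 0.5:
                alt_reads, coverage = 1, int(rng.integers(10, 60))
            else:
                alt_reads, coverage = 2, int(rng.integers(2, 10))
        else:
            coverage = int(rng.integers(10, 200))
            alt_reads = int(rng.integers(2, coverage + 1))
        call = VariantCall(
            protein_id=pid,
            position=pos,
            ref=ref,
            alt=alt,
            alt_reads=alt_reads,
            coverage=coverage,
        )
        calls.append(call)
        truth_rows.append(
            {"label": call.label, "effect": effect, "passes_filters": not fails}
        )
    return calls, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Isoform families


def gen_isoform_family(
    seed=0,
    gene_id: str = "GENE0",
    n_isoforms: int = 3,
    n_shared_blocks: int = 4,
    n_unique_blocks: int = 2,
    block_len: int = 24,
):
    """A gene's isoforms built from shared and isoform-unique exon blocks.

    Each block is a random tryptic-composition segment; every isoform
    carries all shared blocks plus its own unique blocks, giving known
    constitutive and isoform-specific peptides.
    """
    from dialib.proteogenomics import IsoformRecord

    rng = _rng(seed)

    def block() -> str:
        # end each block on K so block boundaries are clean tryptic cuts
        body = "".join(rng.choice(RESIDUES, size=block_len - 1, p=RESIDUE_PROBS))
        return body.replace("P", "A") + "K"

    shared = [block() for _ in range(n_shared_blocks)]
    isoforms = []
    for k in range(n_isoforms):
        unique = [block() for _ in range(n_unique_blocks)]
        seq = "".join(shared) + "".join(unique)
        isoforms.append(
            IsoformRecord(
                gene_id=gene_id,
                transcript_id=f"{gene_id}_T{k}",
                protein_id=f"{gene_id}_P{k}",
                sequence=seq,
            )
        )
    return isoforms
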