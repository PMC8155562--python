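"""Consensus building, best-PSM selection, transition extraction, GTL IO."""

import numpy as np
import pytest

from dialib import chem, simulate
from dialib.io import GTL_COLUMNS, FormatError, read_gtl, write_gtl
from dialib.library import (
    ConsensusSpectrum,
    PSMRecord,
    Spectrum,
    Transition,
    TransitionConfig,
    build_consensus,
    build_library,
    extract_transitions,
    select_best_psms,
)


def spectrum(sid, mz, inten, rt=100.0, cluster_charge=2):
    return Spectrum(
        id=sid,
        precursor_mz=500.0,
        precursor_charge=cluster_charge,
        rt=rt,
        mz=np.asarray(mz, float),
        intensity=np.asarray(inten, float),
    )


class TestConsensus:
    def test_singleton_cluster_is_identity(self):
        s = spectrum("a", [100.0, 200.0], [1.0, 2.0], rt=42.0)
        (cs,) = build_consensus([s], {"a": "c1"})
        assert cs.member_count == 1
        assert cs.rt == 42.0
        np.testing.assert_array_equal(cs.mz, s.mz)
        np.testing.assert_array_equal(cs.intensity, s.intensity)

    def test_identical_members_average_unchanged(self):
        s1 = spectrum("a", [100.0, 200.0], [4.0, 6.0], rt=10.0)
        s2 = spectrum("b", [100.0, 200.0], [4.0, 6.0], rt=20.0)
        (cs,) = build_consensus([s1, s2], {"a": "c1", "b": "c1"})
        np.testing.assert_allclose(cs.mz, [100.0, 200.0])
        np.testing.assert_allclose(cs.intensity, [4.0, 6.0])
        assert cs.rt == 15.0

    def test_merge_tolerance_boundary(self):
        s1 = spectrum("a", [500.000], [1.0])
        s2 = spectrum("b", [500.010], [1.0])
        assign = {"a": "c1", "b": "c1"}
        wide = TransitionConfig(merge_tolerance_da=0.02)
        narrow = TransitionConfig(merge_tolerance_da=0.005)
        (cs,) = build_consensus([s1, s2], assign, wide)
        assert len(cs.mz) == 1
        assert cs.mz[0] == pytest.approx(500.005)
        (cs,) = build_consensus([s1, s2], assign, narrow)
        assert len(cs.mz) == 2

    def test_unknown_spectrum_in_assignment(self):
        s = spectrum("a", [100.0], [1.0])
        with pytest.raises(ValueError, match="unknown"):
            build_consensus([s], {"a": "c1", "ghost": "c1"})

    def test_merged_peak_count_bounded(self, rng):
        members = [
            spectrum(f"s{i}", np.sort(rng.uniform(100, 1000, 40)), rng.uniform(1, 10, 40))
            for i in range(4)
        ]
        (cs,) = build_consensus(members, {s.id: "c" for s in members})
        assert len(cs.mz) <= 160
        assert np.all(np.diff(cs.mz) > 0)


class TestBestPSM:
    def make(self, q, score=1.0, target="t1", peptide="ACDK", charge=2):
        return PSMRecord(target, peptide, charge, score, 0.01, q)

    def test_argmin_q_per_group(self):
        best = select_best_psms([self.make(0.05), self.make(0.02, target="t2")])
        assert best[("ACDK", 2)].qvalue == 0.02

    def test_q_ceiling_is_strict(self):
        assert select_best_psms([self.make(0.15)]) == {}
        assert select_best_psms([self.make(0.10)]) == {}
        assert ("ACDK", 2) in select_best_psms([self.make(0.0999)])

    def test_tie_breaks_to_higher_score_then_id(self):
        a = self.make(0.02, score=3.0, target="t2")
        b = self.make(0.02, score=5.0, target="t9")
        assert select_best_psms([a, b])[("ACDK", 2)] is b
        c = self.make(0.02, score=5.0, target="t1")
        assert select_best_psms([b, c])[("ACDK", 2)] is c

    def test_groups_keyed_by_peptide_and_charge(self):
        psms = [self.make(0.01, charge=2), self.make(0.03, charge=3)]
        best = select_best_psms(psms)
        assert set(best) == {("ACDK", 2), ("ACDK", 3)}


class TestExtraction:
    def consensus_for(self, peptide, mz, inten, cluster="c1", rt=300.0):
        return ConsensusSpectrum(cluster, 1, 500.0, rt, np.asarray(mz, float),
                                 np.asarray(inten, float))

    def psm_for(self, peptide, cluster="c1"):
        return PSMRecord(cluster, peptide, 2, 5.0, 1e-4, 0.01)

    def test_ppm_boundary_inside_and_outside(self):
        pep = "ACDK"
        theo = chem.fragment_mz(pep, "y", 2, 1)
        inside = theo * (1 + 0.5e-6)
        outside = theo * (1 + 2e-6)
        cs = self.consensus_for(pep, [inside], [10.0])
        got = extract_transitions(cs, self.psm_for(pep))
        assert [(t.series, t.ordinal, t.fragment_charge) for t in got] == [("y", 2, 1)]
        cs = self.consensus_for(pep, [outside], [10.0])
        assert extract_transitions(cs, self.psm_for(pep)) == []

    def test_full_theoretical_spectrum_yields_complete_count(self, rng):
        from tests.conftest import random_peptide

        pep = random_peptide(rng, 8, 12)
        cfg = TransitionConfig()
        ions = chem.theoretical_fragments(pep, cfg.series, cfg.fragment_charges)
        mz = sorted(ion.mz for ion in ions)
        cs = self.consensus_for(pep, mz, np.ones(len(mz)))
        got = extract_transitions(cs, self.psm_for(pep), cfg)
        # some theoretical ions may coincide in m/z (shared peak still
        # matches each), so the count is exactly the enumeration size
        assert len(got) == (len(pep) - 1) * len(cfg.series) * len(cfg.fragment_charges)

    def test_closest_peak_wins(self):
        pep = "ACDK"
        theo = chem.fragment_mz(pep, "b", 2, 1)
        near = theo * (1 + 0.2e-6)
        far = theo * (1 - 0.8e-6)
        cs = self.consensus_for(pep, sorted([near, far]), [5.0, 50.0][:: 1 if near > far else -1])
        got = [t for t in extract_transitions(cs, self.psm_for(pep))
               if (t.series, t.ordinal, t.fragment_charge) == ("b", 2, 1)]
        assert got[0].observed_mz == pytest.approx(near)

    def test_group_id_and_rt(self):
        pep = "ACDK"
        theo = chem.fragment_mz(pep, "y", 1, 1)
        cs = self.consensus_for(pep, [theo], [3.0], rt=777.0)
        (t,) = extract_transitions(cs, self.psm_for(pep))
        assert t.group_id == "ACDK/2"
        assert t.normalized_rt == 777.0
        assert t.library_intensity == 3.0

    def test_mismatched_target_raises(self):
        cs = self.consensus_for("ACDK", [100.0], [1.0], cluster="c1")
        with pytest.raises(ValueError):
            extract_transitions(cs, self.psm_for("ACDK", cluster="other"))

    def test_ppm_invariant_holds_for_all_emitted(self, rng):
        peptides = [p.sequence for _, s in simulate.gen_proteome(5, seed=3)
                    for p in chem.digest(s)][:20]
        spectra, assignment, psms, _ = simulate.gen_spectra(peptides, seed=4)
        transitions = build_library(spectra, assignment, psms)
        assert transitions
        for t in transitions:
            theo = chem.fragment_mz(t.peptide, t.series, t.ordinal, t.fragment_charge)
            assert abs(t.product_mz - theo) / theo <= 1.0e-6


class TestRecallAndNoise:
    def test_recall_and_noise_rates_on_jittered_spectra(self):
        """Jitter SD 0.3 ppm + 20% noise peaks: recall >= 0.95 of true
        fragments; <= 2% of emitted transitions come from noise peaks."""
        peptides = [p.sequence for _, s in simulate.gen_proteome(20, seed=5)
                    for p in chem.digest(s)][:120]
        spectra, assignment, psms, truth = simulate.gen_spectra(
            peptides, seed=6, replicates=1, jitter_ppm_sd=0.3, noise_fraction=0.2,
            decoy_fraction=0.0,
        )
        by_cluster = {assignment[s.id]: s for s in spectra}
        n_true = n_found = n_emitted = n_noise = 0
        for psm in psms:
            s = by_cluster[psm.target_id]
            cs = ConsensusSpectrum(psm.target_id, 1, s.precursor_mz, s.rt,
                                   s.mz, s.intensity)
            got = extract_transitions(cs, psm)
            ions = truth.fragments[psm.peptide]
            found = {(t.series, t.ordinal, t.fragment_charge) for t in got}
            n_true += len(ions)
            n_found += sum((i.series, i.ordinal, i.charge) in found for i in ions)
            n_emitted += len(got)
            noise = truth.noise_mz[s.id]
            n_noise += sum(t.observed_mz in noise for t in got)
        assert n_found / n_true >= 0.95
        assert n_noise / n_emitted <= 0.02


class TestGTLRoundTrip:
    def random_transitions(self, rng, n=1000):
        out = []
        for i in range(n):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=8))
            z = int(rng.integers(1, 4))
            ordinal = int(rng.integers(1, len(pep)))
            series = str(rng.choice(["y", "b"]))
            fz = int(rng.integers(1, 3))
            out.append(
                Transition(
                    group_id=f"{pep}/{z}",
                    peptide=pep,
                    precursor_charge=z,
                    precursor_mz=round(float(rng.uniform(300, 1200)), 6),
                    product_mz=round(float(rng.uniform(100, 1500)), 6),
                    series=series,
                    ordinal=ordinal,
                    fragment_charge=fz,
                    library_intensity=float(rng.uniform(1, 1e6)),
                    normalized_rt=round(float(rng.uniform(0, 7200)), 4),
                    protein_name=f"PROT{i % 7}",
                    decoy=bool(rng.integers(0, 2)),
                )
            )
        return out

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_gtl([], path)
        assert path.read_text().strip() == "\t".join(GTL_COLUMNS)
        assert read_gtl(path) == []

    def test_round_trip_preserves_fields(self, rng, tmp_path):
        ts = self.random_transitions(rng)
        path = tmp_path / "lib.tsv"
        write_gtl(ts, path)
        back = read_gtl(path)
        assert len(back) == len(ts)
        for a, b in zip(ts, back):
            assert a.group_id == b.group_id
            assert a.peptide == b.peptide
            assert a.precursor_charge == b.precursor_charge
            assert a.product_mz == pytest.approx(b.product_mz, abs=1e-6)
            assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-6)
            assert (a.series, a.ordinal, a.fragment_charge) == (
                b.series, b.ordinal, b.fragment_charge)
            assert a.decoy == b.decoy

    def test_column_order_is_byte_stable(self, rng, tmp_path):
        ts = self.random_transitions(rng, n=5)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_gtl(ts, p1)
        write_gtl(ts, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.read_text().splitlines()[0] == "\t".join(GTL_COLUMNS)

    def test_shuffled_columns_read_via_header(self, rng, tmp_path):
        ts = self.random_transitions(rng, n=20)
        path = tmp_path / "lib.tsv"
        write_gtl(ts, path)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        perm = list(np.random.default_rng(1).permutation(len(header)))
        shuffled = tmp_path / "shuf.tsv"
        with open(shuffled, "w") as fh:
            fh.write("\t".join(header[i] for i in perm) + "\n")
            for line in lines[1:]:
                fields = line.split("\t")
                fh.write("\t".join(fields[i] for i in perm) + "\n")
        back = read_gtl(shuffled)
        assert [t.group_id for t in back] == [t.group_id for t in ts]

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_gtl([], path)
        with open(path, "a") as fh:
            fh.write("only\tthree\tfields\n")
        with pytest.raises(FormatError, match=":2"):
            read_gtl(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("transition_group_id\tPeptideSequence\n")
        with pytest.raises(FormatError, match="missing columns"):
            read_gtl(path)
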