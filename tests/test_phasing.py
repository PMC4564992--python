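import itertools

import numpy as np
import pytest

from poescan import phasing
from poescan.phasing import (Origin, MendelianInconsistencyError,
                             estimate_origins, estimate_window_haplotypes,
                             mendelian_origin, phase_trio_window,
                             read_shapeit_haps, resolve_duo_origin)
from poescan.pedio import FamilyUnit

from conftest import make_matrix, make_trio_unit


def oracle_origin(gm, gf, gc):
    """Brute-force enumeration of the <=4 ordered transmissions."""
    alleles = {0: [0], 1: [0, 1], 2: [1]}
    trans = [(am, ap) for am in alleles[gm] for ap in alleles[gf]
             if am + ap == gc]
    if not trans:
        return "error"
    if gc != 1:
        return Origin.NOT_APPLICABLE
    origins = {Origin.PATERNAL_MINOR if ap else Origin.MATERNAL_MINOR
               for _, ap in trans}
    return origins.pop() if len(origins) == 1 else Origin.AMBIGUOUS


class TestMendelianOrigin:
    @pytest.mark.parametrize("gm,gf,gc",
                             list(itertools.product(range(3), repeat=3)))
    def test_agrees_with_transmission_enumeration(self, gm, gf, gc):
        expected = oracle_origin(gm, gf, gc)
        if expected == "error":
            with pytest.raises(MendelianInconsistencyError):
                mendelian_origin(gm, gf, gc)
        else:
            assert mendelian_origin(gm, gf, gc).value == expected

    def test_triple_het_is_the_only_ambiguity(self):
        assert mendelian_origin(1, 1, 1).value == Origin.AMBIGUOUS
        for gm, gf, gc in itertools.product(range(3), repeat=3):
            if (gm, gf, gc) != (1, 1, 1) and oracle_origin(gm, gf, gc) != "error":
                assert mendelian_origin(gm, gf, gc).value != Origin.AMBIGUOUS

    def test_forced_calls_carry_certain_posterior(self):
        assert mendelian_origin(2, 0, 1).value == Origin.MATERNAL_MINOR
        call = mendelian_origin(1, 2, 1)
        assert call.value == Origin.PATERNAL_MINOR
        assert call.posterior_paternal == 1.0


class TestPhaseTrioWindow:
    def test_delegates_forced_call(self, small_trio_dataset):
        ds = small_trio_dataset
        unit = ds.units[0]
        gm = ds.genotypes
        for j in range(gm.n_snps):
            trip = (int(gm.dosage_row(unit.mother_id)[j]),
                    int(gm.dosage_row(unit.father_id)[j]),
                    int(gm.dosage_row(unit.child_id)[j]))
            if trip != (1, 1, 1):
                assert (phase_trio_window(unit, gm, j).value
                        == mendelian_origin(*trip).value)

    def test_resolves_with_informative_flank(self):
        # test SNP t = 0 is triple-het; at flank s = 1 the mother is het and
        # her transmission is forced (gf = 0, gc = 1 -> mother sent the
        # minor).  Her diplotype over (t, s) is {11, 00} or {01, 10}; with a
        # pool concentrated on 11/00 the transmitted maternal haplotype
        # carries the minor at t, so the child's minor at t is maternal.
        dos = np.array([[1, 1],    # mother
                        [1, 0],    # father
                        [1, 1]])   # child
        gm = make_matrix(dos, ids=["M", "P", "C"])
        unit = make_trio_unit(mother="M", father="P", child="C")
        freqs = phasing.HaplotypeFrequencies(
            window=np.array([0, 1]),
            haplotypes=[(1, 1), (0, 0), (1, 0), (0, 1)],
            freq=np.array([0.45, 0.45, 0.05, 0.05]),
            loglik_path=[], converged=True)
        call = phase_trio_window(unit, gm, 0, freqs=freqs)
        assert call.value == Origin.MATERNAL_MINOR
        assert call.posterior_paternal < 0.05

    def test_homozygous_flank_carries_no_information(self):
        # when the mother is homozygous at the flank, both phase completions
        # involve the same founder haplotypes, so the posterior stays 1/2
        # whatever the frequencies
        dos = np.array([[1, 0],    # mother
                        [1, 2],    # father
                        [1, 1]])   # child
        gm = make_matrix(dos, ids=["M", "P", "C"])
        unit = make_trio_unit(mother="M", father="P", child="C")
        freqs = phasing.HaplotypeFrequencies(
            window=np.array([0, 1]),
            haplotypes=[(1, 1), (0, 0), (1, 0), (0, 1)],
            freq=np.array([0.4, 0.3, 0.2, 0.1]),
            loglik_path=[], converged=True)
        call = phase_trio_window(unit, gm, 0, freqs=freqs)
        assert call.value == Origin.AMBIGUOUS

    def test_all_window_triple_het_stays_ambiguous(self):
        dos = np.ones((3, 5), dtype=int)
        gm = make_matrix(dos, ids=["M", "P", "C"])
        unit = make_trio_unit(mother="M", father="P", child="C")
        assert phase_trio_window(unit, gm, 2, window_snps=5).value \
            == Origin.AMBIGUOUS

    def test_never_contradicts_forced_calls(self, small_trio_dataset):
        ds = small_trio_dataset
        gm = ds.genotypes
        for j in (3, 11, 19):
            calls = estimate_origins(ds.units, gm, j)
            for unit, call in zip(ds.units, calls):
                trip = (int(gm.dosage_row(unit.mother_id)[j]),
                        int(gm.dosage_row(unit.father_id)[j]),
                        int(gm.dosage_row(unit.child_id)[j]))
                forced = mendelian_origin(*trip)
                if forced.value not in (Origin.AMBIGUOUS,):
                    assert call.value == forced.value

    def test_accuracy_on_ld_blocks(self, small_trio_dataset):
        # ambiguous-call accuracy against simulated truth under block LD
        ds = small_trio_dataset
        gm = ds.genotypes
        total = correct = 0
        for j in range(gm.n_snps):
            calls = estimate_origins(ds.units, gm, j)
            for i, unit in enumerate(ds.units):
                trip = (int(gm.dosage_row(unit.mother_id)[j]),
                        int(gm.dosage_row(unit.father_id)[j]),
                        int(gm.dosage_row(unit.child_id)[j]))
                if trip != (1, 1, 1):
                    continue
                if calls[i].value in (Origin.PATERNAL_MINOR,
                                      Origin.MATERNAL_MINOR):
                    total += 1
                    correct += (calls[i].value
                                == ds.true_origin_call(i, j).value)
        assert total > 50
        assert correct / total > 0.75


class TestWindowHaplotypeEM:
    def _duos(self, dosage_pairs):
        """duo units + matrix from (mother row, child row) pairs."""
        rows, ids, units = [], [], []
        for i, (dm, dc) in enumerate(dosage_pairs):
            rows += [dm, dc]
            ids += [f"M{i}", f"C{i}"]
            units.append(FamilyUnit("duo_mother", f"F{i}", f"C{i}",
                                    mother_id=f"M{i}"))
        return units, make_matrix(np.array(rows), ids=ids)

    def test_single_snp_window_recovers_allele_frequency(self):
        # unambiguous duos only: haplotype frequencies = allele frequencies
        pairs = [([0], [0])] * 6 + [([2], [1])] * 2 + [([0], [1])] * 2
        units, gm = self._duos(pairs)
        freqs = estimate_window_haplotypes(units, gm, 0, window_snps=1)
        table = freqs.as_dict()
        # founder alleles per duo: mother's two plus the father's
        # transmitted one.  (0/0, child 0): 0,0,0; (1/1 mother, child het):
        # 1,1,0 (father sent the major); (0/0 mother, child het): 0,0,1.
        # minor fraction = (2*2 + 2*1)/30 = 0.2
        assert table[(1,)] == pytest.approx(6 / 30, abs=1e-6)

    def test_complete_ld_concentrates_on_two_haplotypes(self):
        pairs = [([0, 0], [1, 1])] * 3 + [([2, 2], [1, 1])] * 3 \
            + [([0, 0], [0, 0])] * 2 + [([2, 2], [2, 2])] * 2
        units, gm = self._duos(pairs)
        freqs = estimate_window_haplotypes(units, gm, 0, window_snps=3)
        table = freqs.as_dict()
        support = {h for h, f in table.items() if f > 1e-6}
        assert support == {(0, 0), (1, 1)}

    def test_em_loglik_nondecreasing(self, small_duo_dataset):
        ds = small_duo_dataset
        freqs = estimate_window_haplotypes(ds.units, ds.genotypes, 12,
                                           window_snps=7)
        path = np.array(freqs.loglik_path)
        assert np.all(np.diff(path) >= -1e-9)
        assert abs(freqs.freq.sum() - 1.0) < 1e-12


class TestResolveDuoOrigin:
    def test_null_hwe_posterior_equals_maf(self):
        # single-SNP window, both het: posterior that the minor allele is
        # paternal equals p (brute-force over father genotypes under HWE)
        for p in (0.1, 0.2, 0.35, 0.5):
            unit = FamilyUnit("duo_mother", "F0", "C0", mother_id="M0")
            gm = make_matrix(np.array([[1], [1]]), ids=["M0", "C0"])
            freqs = phasing.HaplotypeFrequencies(
                window=np.array([0]), haplotypes=[(0,), (1,)],
                freq=np.array([1 - p, p]), loglik_path=[], converged=True)
            call = resolve_duo_origin(unit, gm, 0, freqs)
            if p == 0.5:
                assert call.value == Origin.AMBIGUOUS
            else:
                assert call.posterior_paternal == pytest.approx(p)
                assert call.value == Origin.MATERNAL_MINOR

    def test_concentrated_pool_forces_origin(self):
        # haplotypes (1,0) and (0,1) only; mother 1/1 at both SNPs must be
        # (1,0)+(0,1); child het-het transmitted haplotype matches one pool
        # member, and with child (1,1) both phases are symmetric -- so use an
        # asymmetric pool with hap (1,1) present instead:
        unit = FamilyUnit("duo_mother", "F0", "C0", mother_id="M0")
        gm = make_matrix(np.array([[1, 0], [1, 1]]), ids=["M0", "C0"])
        # mother is (1,0)/(0,0); child (1,1): maternal hap is (1,0) or (0,0)
        # paternal is then (0,1) or (1,1); pool gives (1,1) zero frequency
        freqs = phasing.HaplotypeFrequencies(
            window=np.array([0, 1]), haplotypes=[(1, 0), (0, 0), (0, 1)],
            freq=np.array([0.3, 0.4, 0.3]), loglik_path=[], converged=True)
        call = resolve_duo_origin(unit, gm, 0, freqs)
        assert call.value == Origin.MATERNAL_MINOR
        assert call.posterior_paternal == pytest.approx(0.0)

    def test_delegates_forced_configuration(self):
        unit = FamilyUnit("duo_mother", "F0", "C0", mother_id="M0")
        gm = make_matrix(np.array([[2], [1]]), ids=["M0", "C0"])
        freqs = phasing.HaplotypeFrequencies(
            window=np.array([0]), haplotypes=[(0,), (1,)],
            freq=np.array([0.5, 0.5]), loglik_path=[], converged=True)
        assert resolve_duo_origin(unit, gm, 0, freqs).value \
            == Origin.MATERNAL_MINOR


class TestReadShapeitHaps:
    SAMPLE = "ID_1 ID_2 missing\n0 0 0\nF1 P 0\nF1 M 0\nF1 C 0\n"
    # SNP rows: chr id pos aA aB then 2 columns per sample (P, M, C)
    # P = A/B at snp1, B/B at snp2 ; M = A/A, A/B ; C inherits
    # paternal hap (B at snp1, B at snp2), maternal hap (A, B)
    HAPS = ("1 rs1 1000 A G 0 1 0 0 0 1\n"
            "1 rs2 2000 A G 1 1 0 1 1 1\n")

    def _write(self, tmp_path, haps=None, sample=None):
        hp = tmp_path / "x.haps"
        sp = tmp_path / "x.sample"
        hp.write_text(haps or self.HAPS)
        sp.write_text(sample or self.SAMPLE)
        return hp, sp

    def test_trio_labelling(self, tmp_path):
        hp, sp = self._write(tmp_path)
        unit = make_trio_unit(fid="F1", mother="M", father="P", child="C")
        phased = read_shapeit_haps(hp, sp, [unit])
        assert len(phased) == 1
        pu = phased[0]
        # child hap1 = (0,1) matches mother's second hap; hap2 = (1,1)
        # matches father's second.  Minor alleles from parental haplotypes:
        # G at rs1 (freq 1/4) but A at rs2 (G freq 3/4), so minor-coded
        # child haplotypes are maternal (0,0) and paternal (1,0).
        np.testing.assert_array_equal(pu.child_maternal + pu.child_paternal,
                                      np.array([1, 0]))
        call = pu.origin_call(0)
        assert call.value == Origin.PATERNAL_MINOR
        assert pu.origin_call(1).value == Origin.NOT_APPLICABLE

    def test_row_count_mismatch(self, tmp_path):
        hp, sp = self._write(tmp_path)
        unit = make_trio_unit(fid="F1", mother="M", father="P", child="C")
        with pytest.raises(phasing.PlinkLikeFormatError, match="expected 3"):
            read_shapeit_haps(hp, sp, [unit], expected_snps=3)

    def test_duo_matching_rule(self, tmp_path):
        sample = "ID_1 ID_2 missing\n0 0 0\nF1 M 0\nF1 C 0\n"
        haps = ("1 rs1 1000 A G 0 1 1 0\n"
                "1 rs2 2000 A G 0 1 1 1\n")
        hp, sp = self._write(tmp_path, haps=haps, sample=sample)
        unit = FamilyUnit("duo_mother", "F1", "C", mother_id="M")
        pu = read_shapeit_haps(hp, sp, [unit])[0]
        # child haps: (1,1) and (0,1); mother's: (0,0) and (1,1)
        # -> child (1,1) is maternal, (0,1) paternal
        assert list(pu.child_maternal) != list(pu.child_paternal)

    def test_mismatching_child_dropped(self, tmp_path):
        haps = ("1 rs1 1000 A G 0 1 0 0 1 1\n"
                "1 rs2 2000 A G 1 1 0 1 0 0\n")
        hp, sp = self._write(tmp_path, haps=haps)
        unit = make_trio_unit(fid="F1", mother="M", father="P", child="C")
        with pytest.warns(UserWarning, match="dropped"):
            phased = read_shapeit_haps(hp, sp, [unit], mismatch_tol=0.0)
        assert phased == []
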