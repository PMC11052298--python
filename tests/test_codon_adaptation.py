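"""Codon frequencies, I_TE weights and scores, DITE, effective numbers."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from transelect.codon_adaptation import (
    CodonUsageTable,
    ITEWeights,
    adaptation,
    background_from_gc,
    codon_frequencies,
    effective_number,
    gene_ite,
    ite_weights,
    n_ac,
)
from transelect.genetic_code import AA_TO_CODONS, FAMILY_SIZE
from transelect.genome_io import GeneRecord, TRNAGene


class TestCodonFrequencies:
    def test_start_and_stop_excluded(self):
        table = codon_frequencies(["ATGAAAAAGTAA"])
        assert table.counts == {"AAA": 1, "AAG": 1}

    def test_counts_additive(self):
        one = codon_frequencies(["ATGAAAAAGTAA"])
        two = codon_frequencies(["ATGAAAAAGTAA"] * 2)
        assert two.counts == {c: 2 * v for c, v in one.counts.items()}

    def test_incomplete_gene_skipped(self):
        table = codon_frequencies(["ATGAAAA"])
        assert table.skipped_genes == 1
        assert table.counts == {}

    def test_law_of_large_numbers_recovery(self):
        """Family frequencies from ~1e5 sampled codons match the sampling
        distribution to +/-0.01."""
        rng = np.random.default_rng(101)
        probs = {"GCA": 0.5, "GCC": 0.3, "GCG": 0.15, "GCT": 0.05}
        codons = rng.choice(list(probs), size=100_002, p=list(probs.values()))
        seq = "ATG" + "".join(codons) + "TAA"
        table = codon_frequencies([seq])
        freqs = table.family_frequencies("A")
        for codon, p in probs.items():
            assert freqs[codon] == pytest.approx(p, abs=0.01)


class TestITEWeights:
    def test_no_selection_signal_gives_unit_weights(self):
        heg = CodonUsageTable(counts={"AAA": 50, "AAG": 50})
        bg = CodonUsageTable(counts={"AAA": 500, "AAG": 500})
        w = ite_weights(heg, bg)
        assert w.weights["AAA"] == pytest.approx(1.0)
        assert w.weights["AAG"] == pytest.approx(1.0)

    def test_two_codon_family_ratio(self):
        # frequencies (0.8, 0.2) against a uniform background -> (1, 0.25)
        heg = CodonUsageTable(counts={"AAA": 8000, "AAG": 2000})
        bg = CodonUsageTable(counts={"AAA": 5000, "AAG": 5000})
        w = ite_weights(heg, bg)
        assert w.weights["AAA"] == pytest.approx(1.0)
        assert w.weights["AAG"] == pytest.approx(0.25, abs=1e-3)

    def test_missing_family_defaults_to_one(self):
        heg = CodonUsageTable(counts={"AAA": 10})
        w = ite_weights(heg, 50.0)
        assert all(w.weights[c] == 1.0 for c in AA_TO_CODONS["G"])

    def test_optimal_codons_recovered_from_generator(self, small_panel,
                                                     parsed_species):
        from transelect.codon_adaptation import optimal_codon

        truth = small_panel["manifest"]["species"][0]
        heg = parsed_species.genes("HEG")
        w = ite_weights(codon_frequencies(heg), parsed_species.gc_percent)
        hits = total = 0
        for aa, codon in truth["optimal_codons"].items():
            if FAMILY_SIZE[aa] == 1:
                continue
            total += 1
            hits += optimal_codon(w, aa) == codon
        assert hits / total >= 0.95


class TestGeneITE:
    def test_all_optimal_codons_score_one(self):
        w = ITEWeights(weights={c: 1.0 for cs in AA_TO_CODONS.values()
                                for c in cs})
        assert gene_ite("ATGAAAGGTTAA", w) == pytest.approx(1.0)

    def test_geometric_mean_of_two(self):
        weights = {c: 1.0 for cs in AA_TO_CODONS.values() for c in cs}
        weights["AAG"] = 0.25
        w = ITEWeights(weights=weights)
        # codons scored: AAG (0.25) and GGT (1.0)
        assert gene_ite("ATGAAGGGTTAA", w) == pytest.approx(0.5)

    def test_met_trp_and_start_not_scored(self):
        weights = {c: 0.5 for cs in AA_TO_CODONS.values() for c in cs}
        w = ITEWeights(weights=weights)
        # only Met/Trp codons after the start: nothing scorable
        assert math.isnan(gene_ite("ATGATGTGGTAA", w))

    def test_null_mean_matches_direct_simulation_oracle(self):
        """Mean I_TE of background-drawn genes agrees with an independent
        Monte-Carlo estimate of E[exp(mean log w)]."""
        rng = np.random.default_rng(11)
        codons = ["AAA", "AAG", "GAA", "GAG"]
        weights = {c: 1.0 for cs in AA_TO_CODONS.values() for c in cs}
        weights.update({"AAA": 1.0, "AAG": 0.4, "GAA": 1.0, "GAG": 0.7})
        w = ITEWeights(weights=weights)
        impl = []
        for _ in range(400):
            body = rng.choice(codons, size=100)
            impl.append(gene_ite("ATG" + "".join(body) + "TAA", w))
        oracle_rng = np.random.default_rng(12)
        logw = np.log([weights[c] for c in codons])
        oracle = np.exp(
            logw[oracle_rng.integers(0, 4, size=(4000, 100))].mean(axis=1)
        ).mean()
        assert np.mean(impl) == pytest.approx(oracle, abs=0.01)


class TestDITE:
    def _genes(self, seqs):
        return [GeneRecord(locus_tag=f"g{i}", coding_sequence=s)
                for i, s in enumerate(seqs)]

    def test_difference_of_means(self):
        w = ITEWeights(weights={c: 1.0 for cs in AA_TO_CODONS.values()
                                for c in cs})
        w.weights["AAG"] = 0.25
        heg = self._genes(["ATGAAAGGTTAA"] * 3)       # I_TE = 1
        rest = self._genes(["ATGAAGGGTTAA"] * 3)      # I_TE = 0.5
        res = adaptation(heg, rest, w)
        assert res.dite == pytest.approx(0.5)

    def test_antisymmetric_under_class_swap(self):
        w = ITEWeights(weights={c: 1.0 for cs in AA_TO_CODONS.values()
                                for c in cs})
        w.weights["AAG"] = 0.3
        a = self._genes(["ATGAAGAAATAA"] * 4)
        b = self._genes(["ATGAAAAAATAA"] * 4)
        assert adaptation(a, b, w).dite == pytest.approx(
            -adaptation(b, a, w).dite)

    def test_empty_class_errors(self):
        w = ITEWeights(weights={c: 1.0 for cs in AA_TO_CODONS.values()
                                for c in cs})
        with pytest.raises(ValueError):
            adaptation([], self._genes(["ATGAAATAA"]), w)

    def test_null_classes_give_near_zero_dite(self):
        """Both classes drawn from one distribution: |DITE| < 0.02."""
        rng = np.random.default_rng(3)
        bg = background_from_gc(50.0)
        fams = {aa: (list(cs), np.array([bg.family_frequencies(aa)[c]
                                         for c in cs]))
                for aa, cs in AA_TO_CODONS.items() if FAMILY_SIZE[aa] > 1}
        aas = list(fams)

        def draw_gene():
            body = []
            for aa in rng.choice(aas, size=150):
                cs, p = fams[aa]
                body.append(cs[rng.choice(len(cs), p=p / p.sum())])
            return "ATG" + "".join(body) + "TAA"

        heg = self._genes([draw_gene() for _ in range(200)])
        rest = self._genes([draw_gene() for _ in range(200)])
        w = ite_weights(codon_frequencies(heg), 50.0)
        assert abs(adaptation(heg, rest, w).dite) < 0.02


class TestEffectiveNumber:
    def test_single_unit_per_family_gives_twenty(self):
        fams = {aa: Counter({cs[0]: 7}) for aa, cs in AA_TO_CODONS.items()}
        assert effective_number(fams).value == pytest.approx(20.0)

    def test_uniform_usage_approaches_sixty_one(self):
        fams = {aa: Counter({c: 10_000 for c in cs})
                for aa, cs in AA_TO_CODONS.items()}
        assert effective_number(fams).value == pytest.approx(61.0, abs=0.05)

    @staticmethod
    def _oracle(fams):
        """Independent direct-formula computation of Wright's number."""
        fbar = {}
        for k in (2, 3, 4, 6):
            fs = []
            for aa, units in fams.items():
                if FAMILY_SIZE[aa] != k:
                    continue
                n = sum(units.values())
                if n <= 1:
                    continue
                f = (n * sum((v / n) ** 2 for v in units.values()) - 1) / (n - 1)
                if f > 0:
                    fs.append(f)
            if fs:
                fbar[k] = sum(fs) / len(fs)
        order = [2, 3, 4, 6]
        for k in order:
            if k not in fbar:
                i = order.index(k)
                nb = [fbar[c] for c in order[max(0, i - 1):i + 2]
                      if c != k and c in fbar]
                fbar[k] = sum(nb) / len(nb) if nb else sum(fbar.values()) / len(fbar)
        return min(61.0, 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6])

    def test_random_anticodon_pools_match_oracle(self):
        rng = np.random.default_rng(23)
        from transelect.genetic_code import anticodon_for

        for _ in range(25):
            size = int(rng.integers(45, 131))
            trnas = []
            aas = list(AA_TO_CODONS)
            for aa in aas:  # guarantee coverage
                trnas.append(TRNAGene(aa, anticodon_for(AA_TO_CODONS[aa][0])))
            while len(trnas) < size:
                aa = aas[int(rng.integers(len(aas)))]
                cs = AA_TO_CODONS[aa]
                trnas.append(TRNAGene(aa, anticodon_for(
                    cs[int(rng.integers(len(cs)))])))
            fams = {}
            for t in trnas:
                fams.setdefault(t.amino_acid, Counter())
                fams[t.amino_acid][t.anticodon] += 1
            got = n_ac(trnas).value
            assert got == pytest.approx(self._oracle(fams), abs=1e-9)

    def test_invariant_to_relabeling_and_duplication(self):
        fams = {"K": Counter({"AAA": 3, "AAG": 1}),
                "F": Counter({"TTT": 2, "TTC": 2}),
                "A": Counter({"GCA": 5, "GCC": 1, "GCG": 1, "GCT": 1}),
                "L": Counter({"CTA": 4, "CTC": 2}),
                "I": Counter({"ATA": 2, "ATC": 3})}
        base = effective_number(fams).value
        relabeled = {aa: Counter({f"u{j}": v for j, (_, v) in
                                  enumerate(sorted(units.items()))})
                     for aa, units in fams.items()}
        assert effective_number(relabeled).value == pytest.approx(base, abs=1e-12)
        doubled = {aa: Counter({u: 2 * v for u, v in units.items()})
                   for aa, units in fams.items()}
        oracle = self._oracle(doubled)
        assert effective_number(doubled).value == pytest.approx(oracle, abs=1e-12)


@given(st.floats(min_value=1.0, max_value=99.0))
def test_gc_background_family_frequencies_sum_to_one(gc):
    table = background_from_gc(gc)
    for aa in AA_TO_CODONS:
        freqs = table.family_frequencies(aa)
        assert sum(freqs.values()) == pytest.approx(1.0)
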