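"""Cleavage windows, frequency matrices, consensus and specificity scoring."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mitotails import (
    CleavageWindow,
    ProteinAnnotation,
    build_frequency_matrix,
    consensus,
    extract_window,
    information_content,
    load_packaged_profiles,
    rank_proteases,
    score_specificity,
)
from mitotails.fixtures import synthetic_reference_proteins
from mitotails.motif import PAD_CHAR, SpecificityProfile, slot_names
from mitotails.types import AMINO_ACIDS


class TestWindowExtraction:
    def test_flank_and_first_residue(self):
        prot = synthetic_reference_proteins()["Q9BW92"]
        w = extract_window(prot, 20)
        assert w.as_dict()["P1"] == prot.sequence[18]
        assert w.as_dict()["P1'"] == "L"
        assert PAD_CHAR not in w.residues

    def test_protein_start_pads_all_upstream(self):
        prot = ProteinAnnotation("T", "MAGHKLRSTWAVDEFGHIKL")
        w = extract_window(prot, 1)
        assert all(r == PAD_CHAR for r in w.residues[:10])
        assert w.as_dict()["P1'"] == "M"

    def test_position_three_pads_deep_flank_only(self):
        prot = ProteinAnnotation("T", "MAGHKLRSTWAVDEFGHIKL")
        w = extract_window(prot, 3)
        d = w.as_dict()
        assert d["P2"] == "M" and d["P1"] == "A"
        assert all(d[f"P{i}"] == PAD_CHAR for i in range(3, 11))

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            extract_window(ProteinAnnotation("T", "MAGH"), 9)


class TestFrequencyMatrix:
    def test_single_window_is_one_hot(self):
        prot = ProteinAnnotation("T", "MAGHKLRSTWAVDEFGHIKLNPQRSTVWYA")
        w = extract_window(prot, 15)
        counts, probs = build_frequency_matrix([w])
        for slot, residue in w.as_dict().items():
            assert counts.loc[residue, slot] == 1
            assert probs[slot].max() == 1.0

    def test_probabilities_scale_invariant(self):
        prot = ProteinAnnotation("T", "MAGHKLRSTWAVDEFGHIKLNPQRSTVWYA")
        w = extract_window(prot, 15)
        _, p1 = build_frequency_matrix([w])
        _, p100 = build_frequency_matrix([w] * 100)
        pd.testing.assert_frame_equal(p1, p100)

    def test_counts_match_independent_tally(self, rng):
        windows = [
            CleavageWindow(
                "W", 50,
                tuple(rng.choice(list(AMINO_ACIDS), size=20)),
            )
            for _ in range(60)
        ]
        counts, _ = build_frequency_matrix(windows)
        tally = Counter()
        for w in windows:
            for slot, res in zip(slot_names(), w.residues):
                tally[(res, slot)] += 1
        for (res, slot), n in tally.items():
            assert counts.loc[res, slot] == n
        assert counts.values.sum() == sum(tally.values())

    def test_pads_excluded_from_columns(self):
        prot = ProteinAnnotation("T", "MAGHKLRSTWAVDEFGHIKL")
        counts, probs = build_frequency_matrix([extract_window(prot, 1)])
        assert counts["P5"].sum() == 0
        assert probs["P5"].isna().all()
        assert probs["P1'"].sum() == pytest.approx(1.0)


class TestInformationContent:
    def test_uniform_column_zero_bits(self):
        probs = pd.DataFrame({"P1": [1 / 20] * 20}, index=list(AMINO_ACIDS))
        assert information_content(probs)["P1"] == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_column_max_bits(self):
        col = [0.0] * 20
        col[3] = 1.0
        probs = pd.DataFrame({"P1": col}, index=list(AMINO_ACIDS))
        assert information_content(probs)["P1"] == pytest.approx(math.log2(20))

    def test_bounds_on_random_columns(self, rng):
        raw = rng.random((20, 5))
        probs = pd.DataFrame(raw / raw.sum(axis=0), index=list(AMINO_ACIDS),
                             columns=[f"P{i}" for i in range(5, 0, -1)])
        ic = information_content(probs)
        assert ((ic >= 0) & (ic <= math.log2(20) + 1e-12)).all()


class TestConsensus:
    def _windows_from_generator(self, n_sites=250):
        from mitotails.annotate import PROCESSED_CATEGORIES, call_nterm_peptides
        from mitotails.simulate import SimulationConfig, _first_tryptic, generate_proteome

        config = SimulationConfig(n_proteins=260, fraction_mitochondrial=0.6,
                                  internal_rate=1.0, seed=23)
        proteins, truth = generate_proteome(config)
        peptides = []
        for acc in sorted(proteins):
            pt = truth.proteins[acc]
            for start in [pt.mature_start, *pt.internal_sites]:
                pep = _first_tryptic(proteins[acc].sequence, start, 6, 3)
                if pep:
                    peptides.append((pep, acc))
        calls = call_nterm_peptides(peptides, proteins)
        windows = [
            extract_window(proteins[c.accession], c.p1_prime)
            for c in calls
            if c.category in PROCESSED_CATEGORIES
        ]
        assert len(windows) >= n_sites
        return windows

    def test_injected_motif_recovered_as_consensus(self):
        """The generator's Arg-Arg-Arg|Ala-Ser processing motif emerges."""
        windows = self._windows_from_generator()
        _, probs = build_frequency_matrix(windows)
        assert "RRR↓AS" in consensus(probs, min_freq=0.2)

    def test_consensus_invariant_to_order_and_duplication(self):
        windows = self._windows_from_generator()[:100]
        _, p_fwd = build_frequency_matrix(windows)
        _, p_dup = build_frequency_matrix(windows[::-1] + windows)
        assert consensus(p_fwd) == consensus(p_dup)


class TestSpecificityScoring:
    def _uniform_profile(self, positions=("P2", "P1", "P1'", "P2'")):
        w = pd.DataFrame(1 / 20, index=list(AMINO_ACIDS), columns=list(positions))
        return SpecificityProfile("uniform", w)

    def test_background_profile_scores_zero(self):
        prot = ProteinAnnotation("T", "MAGHKLRSTWAVDEFGHIKLNPQRSTVWYA")
        w = extract_window(prot, 15)
        assert score_specificity(w, self._uniform_profile()) == pytest.approx(0.0)

    def test_one_hot_match_scores_4_log2_20(self):
        prot = ProteinAnnotation("T", "MAGHKLRSTWAVDEFGHIKLNPQRSTVWYA")
        w = extract_window(prot, 15)
        d = w.as_dict()
        positions = ["P2", "P1", "P1'", "P2'"]
        weights = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=positions)
        for pos in positions:
            weights.loc[d[pos], pos] = 1.0
        score = score_specificity(w, SpecificityProfile("onehot", weights))
        assert score == pytest.approx(4 * math.log2(20))

    def test_all_pad_overlap_not_applicable(self):
        w = CleavageWindow("T", 1, tuple([PAD_CHAR] * 10 + list("MAGHKLRSTW")))
        prof = self._uniform_profile(positions=("P4", "P3", "P2", "P1"))
        assert score_specificity(w, prof) is None

    def test_generating_protease_ranks_first(self, rng):
        """Windows sampled from one protease's specificity rank it on top."""
        positions = ["P2", "P1", "P1'", "P2'"]
        preferred = {"P2": "D", "P1": "E", "P1'": "F", "P2'": "G"}
        weights = pd.DataFrame(0.15 / 19, index=list(AMINO_ACIDS), columns=positions)
        for pos, res in preferred.items():
            weights.loc[res, pos] = 0.85
        generator = SpecificityProfile("GEN.001", weights)
        profiles = load_packaged_profiles() + [generator]
        slots = slot_names()
        top = 0
        n_trials = 200
        for _ in range(n_trials):
            residues = []
            for slot in slots:
                if slot in generator.positions:
                    w = generator.weights[slot].to_numpy()
                    residues.append(str(rng.choice(list(AMINO_ACIDS), p=w / w.sum())))
                else:
                    residues.append(str(rng.choice(list(AMINO_ACIDS))))
            window = CleavageWindow("S", 50, tuple(residues))
            ranking = rank_proteases([window], profiles)
            top += ranking.iloc[0]["protease_id"] == "GEN.001"
        assert top / n_trials >= 0.95

    def test_rank_ties_alphabetical(self):
        prot = ProteinAnnotation("T", "MAGHKLRSTWAVDEFGHIKLNPQRSTVWYA")
        w = extract_window(prot, 15)
        a = self._uniform_profile()
        b = SpecificityProfile("aaa-first", a.weights.copy())
        ranking = rank_proteases([w], [a, b])
        assert ranking["protease_id"].tolist() == ["aaa-first", "uniform"]


def test_packaged_profiles_are_normalized():
    profiles = load_packaged_profiles()
    assert {p.protease_id for p in profiles} == {"M13.001", "M16.003", "S1C.002"}
    for p in profiles:
        np.testing.assert_allclose(p.weights.sum(axis=0), 1.0, atol=1e-9)
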