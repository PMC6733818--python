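import numpy as np
import pytest

from satconnect._align import bases_match, revcomp
from satconnect.errors import SatconnectError
from satconnect.satstats import (
    CENPB_BOX,
    CenpBMotif,
    ConsensusMonomer,
    build_consensus,
    concerted_evolution_test,
    digest_array,
    identity_matrix,
    intra_identity,
    scan_cenpb,
)
from satconnect.seqio import SequenceRecord
from satconnect.simsat import build_array

from _oracles import naive_motif_scan
from conftest import mutate, random_seq


def rec(name, bases):
    return SequenceRecord(id=name, bases=bases)


class TestBuildConsensus:
    def test_identical_clones_reproduce_clone(self, monomer):
        clones = [rec(f"c{i}", monomer) for i in range(10)]
        consensus = build_consensus(clones, species="sp")
        assert consensus.bases == monomer
        assert consensus.depth == 10
        assert not set(consensus.bases) - set("ACGT")

    def test_majority_column(self):
        base = "ACGTACGTACGTACGTACGTACGTACGT"
        variant = base[:5] + "G" + base[6:]  # A/A/G at column 5 -> A
        clones = [rec("a", base), rec("b", base), rec("c", variant)]
        assert build_consensus(clones).bases == base

    def test_tie_becomes_iupac_code(self):
        base = "ACGTACGTACGTACGTACGTACGTACGT"
        variant = base[:4] + "G" + base[5:]  # A/A/G/G at column 4 -> R
        clones = [rec("a", base), rec("b", base),
                  rec("c", variant), rec("d", variant)]
        expected = base[:4] + "R" + base[5:]
        assert build_consensus(clones).bases == expected

    def test_minimum_depth_enforced(self, monomer):
        with pytest.raises(SatconnectError):
            build_consensus([rec("only", monomer)])

    def test_agrees_with_mafft_consensus_on_clean_clones(self, monomer, rng):
        """Independent cross-check: majority consensus over a mafft MSA of
        lightly diverged clones equals ours (substitution-only divergence)."""
        import shutil
        import subprocess
        import tempfile
        from collections import Counter
        from pathlib import Path

        if shutil.which("mafft") is None:
            pytest.skip("mafft not on PATH")
        clones = [
            rec(f"c{i}", mutate(monomer, rng.choice(345, size=3, replace=False), rng))
            for i in range(6)
        ]
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "clones.fasta"
            fasta.write_text("".join(f">{c.id}\n{c.bases}\n" for c in clones))
            out = subprocess.run(
                ["mafft", "--retree", "2", "--quiet", str(fasta)],
                capture_output=True, text=True, check=True,
            ).stdout
        rows = []
        for chunk in out.split(">")[1:]:
            lines = chunk.splitlines()
            rows.append("".join(lines[1:]).upper())
        mafft_consensus = []
        for col in zip(*rows):
            counts = Counter(c for c in col if c != "-")
            if not counts or col.count("-") > len(rows) / 2:
                continue
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                continue  # skip tied columns: tie encoding differs by tool
            mafft_consensus.append(top[0][0])
        ours = build_consensus(clones).bases
        assert len(ours) == len(mafft_consensus) == 345
        disagreements = sum(
            1 for a, b in zip(ours, mafft_consensus)
            if not bases_match(a, b)
        )
        assert disagreements == 0


class TestIdentityMatrix:
    def test_identical_clones_have_100_intra(self, monomer):
        groups = {"sp": [rec(f"c{i}", monomer) for i in range(4)]}
        intra = identity_matrix(groups, "intra")
        assert intra["sp"] == 100.0

    def test_intra_is_mean_over_pairs(self, monomer, rng):
        a = monomer
        b = mutate(monomer, rng.choice(345, size=10, replace=False), rng)
        clones = [rec("a", a), rec("a2", a), rec("b", b)]
        # pairs: (a,a2)=1.0, (a,b)=(a2,b)=335/345
        expected = 100.0 * (1.0 + 2 * (335 / 345)) / 3
        assert intra_identity(clones) == pytest.approx(expected, abs=0.01)

    def test_seven_of_350_differences_give_98_inter(self, rng):
        base = random_seq(rng, 350)
        other = mutate(base, rng.choice(350, size=7, replace=False), rng)
        groups = {
            "g1": [rec("g1a", base), rec("g1b", base)],
            "g2": [rec("g2a", other), rec("g2b", other)],
        }
        inter = identity_matrix(groups, "inter")
        assert inter.get("g1", "g2") == pytest.approx(98.0, abs=0.01)

    def test_symmetric_with_diagonal_100(self, monomer, rng):
        groups = {
            f"g{k}": [
                rec(f"g{k}c{i}",
                    mutate(monomer, rng.choice(345, size=5 * k, replace=False),
                           rng))
                for i in range(2)
            ]
            for k in range(3)
        }
        inter = identity_matrix(groups, "inter")
        assert np.allclose(inter.values, inter.values.T)
        assert np.allclose(np.diag(inter.values), 100.0)
        assert (inter.values >= 0).all() and (inter.values <= 100).all()

    def test_ambiguity_code_matches_contained_base(self):
        c1 = ConsensusMonomer("g1", "ACGTACGTACGTACGTACGTACGTR", 2)
        c2 = ConsensusMonomer("g2", "ACGTACGTACGTACGTACGTACGTA", 2)
        groups = {"g1": [], "g2": []}
        inter = identity_matrix(
            groups, "inter", consensuses={"g1": c1, "g2": c2}
        )
        assert inter.get("g1", "g2") == 100.0  # R contains A


class TestConcertedEvolutionTest:
    def _inter(self, labels, value):
        from satconnect.satstats import IdentityMatrix

        n = len(labels)
        values = np.full((n, n), value)
        np.fill_diagonal(values, 100.0)
        return IdentityMatrix(labels=list(labels), values=values)

    def test_no_flags_when_intra_dominates(self):
        intra = {"a": 99.0, "b": 99.0}
        assert concerted_evolution_test(intra, self._inter("ab", 90.0)) == []

    def test_flag_when_inter_exceeds_intra(self):
        intra = {"a": 79.2, "b": 99.0}
        flags = concerted_evolution_test(intra, self._inter("ab", 85.0))
        assert ("a", "b") in flags
        assert ("b", "a") not in flags

    def test_label_mismatch_rejected(self):
        with pytest.raises(SatconnectError):
            concerted_evolution_test({"a": 1.0}, self._inter("ab", 90.0))


class TestScanCenpB:
    def test_verbatim_motif_scores_nine(self):
        motif_instance = "CTTCGTTGGAAACGGGA"  # concrete CENP-B box
        seq = "AC" * 50 + motif_instance + "AG" * 50  # flanks cannot score 9
        hit = scan_cenpb(ConsensusMonomer("sp", seq, 2))
        assert hit.critical_matches == 9
        assert hit.offset == 100
        assert hit.window == motif_instance

    def test_reverse_strand_detection(self, rng):
        motif_instance = "CTTCGTTGGAAACGGGA"
        fwd = random_seq(rng, 60) + motif_instance + random_seq(rng, 60)
        hit_fwd = scan_cenpb(ConsensusMonomer("sp", fwd, 2))
        hit_rev = scan_cenpb(ConsensusMonomer("sp", revcomp(fwd), 2))
        assert hit_fwd.critical_matches == hit_rev.critical_matches == 9
        assert hit_rev.strand == "-"

    def test_random_consensus_equals_exhaustive_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            seq = random_seq(rng, 345)
            hit = scan_cenpb(ConsensusMonomer("sp", seq, 2))
            crit, strand, offset = naive_motif_scan(
                seq, CENPB_BOX.sequence, CENPB_BOX.critical_positions,
                bases_match,
            )
            assert hit.critical_matches == crit
            assert (hit.strand, hit.offset) == (strand, offset)

    def test_matched_positions_subset_of_criticals(self, rng):
        hit = scan_cenpb(ConsensusMonomer("sp", random_seq(rng, 345), 2))
        assert set(hit.matched_positions) <= set(CENPB_BOX.critical_positions)
        assert len(hit.matched_positions) == hit.critical_matches

    def test_custom_motif_configuration(self):
        motif = CenpBMotif(sequence="AAAATTTT", critical_positions=(0, 1, 2, 3))
        hit = scan_cenpb(ConsensusMonomer("sp", "GGGGAAAATTTTGGGG", 2), motif)
        assert hit.critical_matches == 4
        assert hit.offset == 4


class TestDigestArray:
    def test_tandem_array_with_one_site_per_monomer(self, monomer):
        array = build_array([rec("m", monomer)], copies=10, seed=0)
        profile = digest_array(array, "CCGG", monomer_length=345)
        lengths = sorted(profile.fragment_lengths)
        assert sum(lengths) == 3450
        assert lengths.count(345) == 9  # internal monomer-length fragments
        assert len(lengths) == 11
        assert sum(l for l in lengths if l != 345) == 345  # the two ends

    def test_no_sites_single_fragment(self):
        array = rec("a", "ATATATAT" * 50)
        profile = digest_array(array, "CCGG", monomer_length=345)
        assert profile.fragment_lengths == [len(array.bases)]

    def test_cut_convention_one_base_into_site(self):
        array = rec("a", "AAAACCGGTTTT")
        profile = digest_array(array, "CCGG", monomer_length=6)
        assert profile.fragment_lengths == [5, 7]  # AAAAC | CGGTTTT

    def test_length_conservation_on_random_arrays(self, rng):
        for _ in range(20):
            bases = random_seq(rng, int(rng.integers(100, 2000)))
            profile = digest_array(rec("a", bases), "CCGG", 345)
            assert sum(profile.fragment_lengths) == len(bases)

    def test_ablation_zero_collapses_ladder_to_monomer_rung(self, monomer):
        array = build_array([rec("m", monomer)], copies=50,
                            site_ablation_prob=0.0, seed=1)
        ladder = digest_array(array, "CCGG", 345).ladder()
        # all internal fragments on the 1-mer rung; ends contribute <=2 more
        assert ladder[1] >= 49

    def test_geometric_rung_decay_at_q_03(self, monomer):
        q = 0.3
        n = 10_000
        array = build_array([rec("m", monomer)], copies=n,
                            site_ablation_prob=q, seed=12345)
        ladder = digest_array(array, "CCGG", 345).ladder()
        for k in (1, 2, 3, 4):
            expected = (1 - q) ** 2 * q ** (k - 1)
            observed = ladder.get(k, 0) / n
            sd = (expected * (1 - expected) / n) ** 0.5
            assert observed == pytest.approx(expected, abs=max(5 * sd, 2 / n))


def test_intra_identity_approaches_100_at_zero_mutation(monomer):
    from satconnect.simsat import SimulationConfig, evolve_library

    config = SimulationConfig(mode="frozen", substitution_rate=0.0,
                              library_size=4, seed=0)
    libraries = evolve_library(config)
    for clones in libraries.values():
        assert intra_identity(clones) == 100.0
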