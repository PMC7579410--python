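import itertools

import numpy as np
import pytest

from plasmalfq.datatypes import ProteinRecord
from plasmalfq.duplicates import (
    DuplicatePair,
    classify_scenarios,
    correlate_identity_sharing,
    find_duplicates,
    pairwise_identity,
    shared_peptide_fraction,
    summary_table,
)
from plasmalfq.grouping import PeptideIndex, assemble_groups, build_peptide_index
from plasmalfq.simulate import simulate_paralog_pair, _random_sequence

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# independent affine-gap global aligner (Gotoh), used only as a test oracle
# ---------------------------------------------------------------------------

def gotoh_identity(a, b, match=1.0, mismatch=-1.0, gap_open=-10.0, gap_ext=-0.5):
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_ext * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_ext)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_ext)
    # traceback from the best terminal state
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    cols = []
    while i > 0 or j > 0:
        if state == 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            cols.append((a[i - 1], b[j - 1]))
            i, j, state = i - 1, j - 1, prev
        elif state == 1:
            prev = 0 if M[i - 1, j] + gap_open >= X[i - 1, j] + gap_ext else 1
            cols.append((a[i - 1], "-"))
            i, state = i - 1, prev
        else:
            prev = 0 if M[i, j - 1] + gap_open >= Y[i, j - 1] + gap_ext else 2
            cols.append(("-", b[j - 1]))
            j, state = j - 1, prev
    cols.reverse()
    # trim to the shorter sequence's aligned span
    short = 0 if n <= m else 1
    idx = [k for k, c in enumerate(cols) if c[short] != "-"]
    cols = cols[idx[0]: idx[-1] + 1]
    matches = sum(1 for x, y in cols if x == y and x != "-")
    return 100.0 * matches / len(cols)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = _random_sequence(np.random.default_rng(0), 100)
        assert pairwise_identity(seq, seq) == 100.0

    def test_single_substitution_counting(self):
        a = "ACDEFGHIKL"
        b = "ACDEFGHIKV"
        assert pairwise_identity(a, b) == pytest.approx(90.0)

    def test_terminal_overhang_trimmed(self):
        # the extension beyond the shorter protein must not count
        core = "ACDEFGHIKLMNPQRSTVWY" * 3
        assert pairwise_identity(core, core + "WWWWW") == pytest.approx(100.0)

    def test_agreement_with_gotoh_oracle(self):
        rng = np.random.default_rng(33)
        for trial in range(50):
            length = int(rng.integers(30, 70))
            a = _random_sequence(rng, length)
            b = list(a)
            for pos in rng.choice(length, size=int(rng.integers(0, length // 4)), replace=False):
                b[pos] = AA[rng.integers(20)]
            b = "".join(b)
            if rng.random() < 0.5:  # occasional indel
                cut = int(rng.integers(1, 5))
                b = b[cut:]
            got = pairwise_identity(a, b)
            want = gotoh_identity(a, b)
            assert got == pytest.approx(want, abs=0.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")


class TestSharedPeptideFraction:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 100.0),
            ({"x"}, {"y"}, 0.0),
            ({"a", "b", "c", "d"}, {"c", "d", "e"}, 100 * 2 / 3),
        ],
    )
    def test_arithmetic(self, a, b, expected):
        assert shared_peptide_fraction(a, b) == pytest.approx(expected)

    def test_nested_sets_score_full(self):
        assert shared_peptide_fraction({"a", "b", "c"}, {"a", "b"}) == 100.0

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            shared_peptide_fraction(set(), set())


class TestFindDuplicates:
    def _paralogs(self, identity, seed, fam=0):
        rng = np.random.default_rng(seed)
        return simulate_paralog_pair(_random_sequence(rng, 200), identity, seed, family=fam)

    def test_pair_above_cutoff_reported(self):
        recs = list(self._paralogs(90, 1))
        pairs = find_duplicates(recs)
        assert len(pairs) == 1
        assert pairs[0].identity_pct == pytest.approx(90.0, abs=1.0)

    def test_pair_below_cutoff_not_reported(self):
        recs = list(self._paralogs(60, 2))
        assert find_duplicates(recs) == []

    def test_same_gene_isoforms_skipped(self):
        seq = _random_sequence(np.random.default_rng(3), 150)
        recs = [
            ProteinRecord("A1", seq, gene_id="g1"),
            ProteinRecord("A2", seq, gene_id="g1"),
        ]
        assert find_duplicates(recs) == []

    def test_equals_brute_force_on_small_proteome(self):
        rng = np.random.default_rng(4)
        recs = []
        for fam in range(6):
            a, b = self._paralogs(float(rng.uniform(60, 100)), int(rng.integers(1e6)), fam)
            recs.extend([a, b])
        for i in range(6):
            recs.append(ProteinRecord(f"S{i}", _random_sequence(rng, int(rng.integers(100, 300)))))
        got = {(p.acc_a, p.acc_b) for p in find_duplicates(recs)}
        expect = set()
        for ra, rb in itertools.combinations(recs, 2):
            if ra.gene_id is not None and ra.gene_id == rb.gene_id:
                continue
            la, lb = len(ra.sequence), len(rb.sequence)
            if 100 * min(la, lb) / max(la, lb) <= 70:
                continue
            if pairwise_identity(ra.sequence, rb.sequence) > 70:
                expect.add(tuple(sorted((ra.accession, rb.accession))))
        assert got == expect


class TestScenarios:
    def _setup(self, identity, detectability=1.0):
        rec_a, rec_b = simulate_paralog_pair(
            _random_sequence(np.random.default_rng(8), 300), identity, seed=8
        )
        index = build_peptide_index([rec_a, rec_b], detectability=detectability, seed=8)
        groups = assemble_groups(index)
        pairs = find_duplicates([rec_a, rec_b], identity_cutoff=50)
        gene_map = {r.accession: r.gene_id for r in (rec_a, rec_b)}
        return groups, pairs, index, gene_map

    def test_cogroupe_pair_is_scenario_i(self):
        groups, pairs, index, gene_map = self._setup(100.0)
        summary, annotated = classify_scenarios(groups, pairs, index=index, gene_map=gene_map)
        assert summary.n_scenario_i == 1 and summary.n_scenario_ii == 0
        assert annotated[0].same_mpg and annotated[0].shared_pct == 100.0

    def test_split_pair_is_scenario_ii(self):
        groups, pairs, index, gene_map = self._setup(72.0)
        assert len(groups) == 2  # divergent paralogs do not co-group
        summary, annotated = classify_scenarios(groups, pairs, index=index, gene_map=gene_map)
        assert summary.n_scenario_ii == 2 and summary.n_scenario_i == 0
        assert not annotated[0].same_mpg

    def test_scenario_counts_partition_groups(self):
        rng = np.random.default_rng(12)
        recs = []
        for fam in range(8):
            a, b = simulate_paralog_pair(
                _random_sequence(rng, 150), float(rng.uniform(70, 100)), seed=12, family=fam
            )
            recs.extend([a, b])
        index = build_peptide_index(recs)
        groups = assemble_groups(index)
        pairs = find_duplicates(recs)
        gene_map = {r.accession: r.gene_id for r in recs}
        summary, _ = classify_scenarios(groups, pairs, index=index, gene_map=gene_map)
        assert summary.total == len(groups)

    def test_identity_extremes_match_construction(self):
        """Near-identical paralogs co-group; divergent ones split."""
        for identity, same in [(99.5, True), (75.0, False)]:
            groups, pairs, index, gene_map = self._setup(identity)
            _, annotated = classify_scenarios(groups, pairs, index=index, gene_map=gene_map)
            assert annotated[0].same_mpg is same

    def test_ss4r_flag_from_chromosome_pairing(self):
        groups, pairs, index, gene_map = self._setup(95.0)
        chrom_map = {p: f"7{s}" for p, s in zip(sorted(gene_map), "ab")}
        homeologs = {frozenset(("7a", "7b"))}
        _, annotated = classify_scenarios(
            groups, pairs, index=index, gene_map=gene_map,
            homeolog_pairs=homeologs, chromosome_map=chrom_map,
        )
        assert annotated[0].is_ss4r is True

    def test_unknown_accession_errors(self):
        groups, pairs, index, gene_map = self._setup(95.0)
        rogue = [DuplicatePair("ZZ1", "ZZ2", 90.0)]
        with pytest.raises(ValueError, match="absent"):
            classify_scenarios(groups, rogue, index=index)


class TestIdentitySharingCorrelation:
    def _gradient_pairs(self, n=50, seed=44, detectability=0.9):
        rng = np.random.default_rng(seed)
        pairs = []
        for fam in range(n):
            identity = float(rng.uniform(70, 100))
            a, b = simulate_paralog_pair(
                _random_sequence(rng, 250), identity, seed=seed, family=fam
            )
            index = build_peptide_index([a, b], detectability=detectability, seed=fam)
            shared = shared_peptide_fraction(
                index.protein_to_peptides[a.accession],
                index.protein_to_peptides[b.accession],
            )
            pairs.append(
                DuplicatePair(a.accession, b.accession, identity, shared_pct=shared,
                              same_mpg=True)
            )
        return pairs

    def test_perfect_line(self):
        pairs = [
            DuplicatePair("A", "B", 80.0, shared_pct=80.0, same_mpg=True),
            DuplicatePair("C", "D", 90.0, shared_pct=90.0, same_mpg=True),
            DuplicatePair("E", "F", 95.0, shared_pct=95.0, same_mpg=True),
        ]
        r, _ = correlate_identity_sharing(pairs, "same_mpg")
        assert r == pytest.approx(1.0)

    def test_simulated_gradient_positive(self):
        r, p = correlate_identity_sharing(self._gradient_pairs(), "same_mpg")
        assert r > 0 and p < 0.05

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.uniform(70, 100, n)
            y = rng.uniform(0, 100, n)
            pairs = [
                DuplicatePair(f"A{i}", f"B{i}", x[i], shared_pct=y[i], same_mpg=True)
                for i in range(n)
            ]
            r, _ = correlate_identity_sharing(pairs, "same_mpg")
            cx, cy = x - x.mean(), y - y.mean()
            expect = (cx * cy).sum() / np.sqrt((cx**2).sum() * (cy**2).sum())
            assert r == pytest.approx(expect, abs=1e-10)

    def test_zero_variance_errors(self):
        pairs = [
            DuplicatePair(f"A{i}", f"B{i}", 90.0, shared_pct=float(i), same_mpg=True)
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="variance"):
            correlate_identity_sharing(pairs, "same_mpg")

    def test_sharing_monotone_in_identity(self):
        """Binned mean sharing is non-decreasing across the identity range."""
        pairs = self._gradient_pairs(n=200, seed=66, detectability=1.0)
        ident = np.array([p.identity_pct for p in pairs])
        shared = np.array([p.shared_pct for p in pairs])
        bins = np.digitize(ident, [70, 80, 90, 100])
        means = [shared[bins == b].mean() for b in sorted(set(bins))]
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))


def test_summary_table_strata():
    pairs = [
        DuplicatePair("A", "B", 95.0, shared_pct=90.0, same_mpg=True, is_ss4r=True),
        DuplicatePair("C", "D", 85.0, shared_pct=40.0, same_mpg=False, is_ss4r=True),
        DuplicatePair("E", "F", 88.0, shared_pct=55.0, same_mpg=False, is_ss4r=False),
    ]
    table = summary_table(pairs)
    assert set(table["stratum"]) == {"same_mpg", "different_mpg"}
    row = table[(table.stratum == "different_mpg") & (table.ss4r == "ss4r")].iloc[0]
    assert row["identity_mean"] == pytest.approx(85.0)
    assert row["n_pairs"] == 1
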