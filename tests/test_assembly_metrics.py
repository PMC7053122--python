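"""Contiguity statistics: contig splitting, N(X)/NG(X), full-assembly metrics."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from asmqc.assembly_metrics import (
    assembly_metrics,
    ng_curve,
    nx_from_lengths,
    split_into_contigs,
)
from asmqc.sequence_io import SequenceRecord


def brute_force_nx(lengths, reference_size, threshold):
    """Independent oracle: examine every prefix of the descending-sorted list."""
    desc = sorted(lengths, reverse=True)
    target = threshold / 100.0 * reference_size
    for i in range(len(desc)):
        if sum(desc[: i + 1]) >= target:
            return desc[i], i + 1
    return None, None


class TestSplitIntoContigs:
    @pytest.mark.parametrize(
        "seq, min_gap, expected",
        [
            ("ACGT" + "N" * 10 + "ACGT", 10, [(0, 4), (14, 4)]),
            ("ACGTNNNACGT", 10, [(0, 11)]),
            ("N" * 12, 10, []),
            ("NNNNNNNNNNNNACGT", 10, [(12, 4)]),
            ("acgtnnnnnnnnnnACGT", 10, [(0, 4), (14, 4)]),  # lowercase gap splits too
        ],
    )
    def test_splitting(self, seq, min_gap, expected):
        assert split_into_contigs(seq, min_gap) == expected

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300), st.integers(1, 20))
    def test_conservation_of_bases(self, seq, min_gap):
        """Contig bases plus splitting-gap bases reconstruct the sequence length."""
        spans = split_into_contigs(seq, min_gap)
        contig_bases = sum(length for _, length in spans)
        # every base outside a contig span must be N
        covered = set()
        for start, length in spans:
            covered.update(range(start, start + length))
        outside = [i for i in range(len(seq)) if i not in covered]
        assert all(seq[i] in "Nn" for i in outside)
        assert contig_bases + len(outside) == len(seq)


class TestNxFromLengths:
    @pytest.mark.parametrize(
        "lengths, ref, thr, expected",
        [
            ([80, 70, 50, 40, 30, 20], 290, 50, (70, 2)),
            ([80, 70, 50, 40, 30, 20], 400, 50, (50, 3)),
            ([80, 70, 50, 40, 30, 20], 400, 90, (None, None)),
        ],
    )
    def test_worked_examples(self, lengths, ref, thr, expected):
        assert nx_from_lengths(lengths, ref, thr) == expected
        assert brute_force_nx(lengths, ref, thr) == expected

    @pytest.mark.parametrize("thr", [0, 101, -5])
    def test_threshold_range_enforced(self, thr):
        with pytest.raises(ValueError):
            nx_from_lengths([10, 20], 30, thr)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            nx_from_lengths([], 10, 50)
        with pytest.raises(ValueError):
            nx_from_lengths([5, 0], 10, 50)

    def test_matches_brute_force_on_random_lists(self):
        rng = random.Random(7)
        for _ in range(200):
            lengths = [rng.randint(1, 1000) for _ in range(rng.randint(1, 30))]
            ref = rng.randint(1, 2 * sum(lengths))
            for thr in (1, 25, 50, 75, 100):
                assert nx_from_lengths(lengths, ref, thr) == brute_force_nx(lengths, ref, thr)


class TestNgCurve:
    def test_single_sequence_flat_curve(self):
        c = ng_curve([123], 123)
        assert all(v == 123 for v in c.values)
        assert all(l == 1 for l in c.l_values)

    def test_consistency_with_pointwise(self):
        lengths = [80, 70, 50, 40, 30, 20]
        c = ng_curve(lengths, 290)
        for t in range(1, 101):
            assert (c.values[t - 1], c.l_values[t - 1]) == nx_from_lengths(lengths, 290, t)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(1, 10_000), min_size=1, max_size=40),
        st.integers(1, 500_000),
    )
    def test_monotonicity_and_undefined_tail(self, lengths, ref):
        c = ng_curve(lengths, ref)
        defined = [(v, l) for v, l in zip(c.values, c.l_values) if v is not None]
        for (v1, l1), (v2, l2) in zip(defined, defined[1:]):
            assert v2 <= v1
            assert l2 >= l1
        # once undefined, undefined for all larger thresholds
        undef = [v is None for v in c.values]
        assert undef == sorted(undef)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=40))
    def test_ng_equals_n_at_assembly_total(self, lengths):
        total = sum(lengths)
        n_curve = ng_curve(lengths, total)
        assert all(v is not None for v in n_curve.values)
        for t in range(1, 101):
            assert (n_curve.values[t - 1], n_curve.l_values[t - 1]) == brute_force_nx(
                lengths, total, t
            )


class TestAssemblyMetrics:
    def test_single_clean_record(self):
        sc, ct = assembly_metrics([SequenceRecord(id="s", seq="ACGTACGT")])
        assert sc.total_bases == 8
        assert sc.n50 == 8 and sc.l50 == 1
        assert sc.gc_percent == 50.0 and sc.n_percent == 0.0
        assert sc.ng50 is None
        assert ct.total_bases == 8  # no gaps: contigs == scaffolds

    def test_multi_record_with_genome_size(self):
        recs = [
            SequenceRecord(id=f"s{i}", seq="A" * n)
            for i, n in enumerate([80, 70, 50, 40, 30, 20])
        ]
        sc, _ = assembly_metrics(recs, estimated_genome_size=400)
        assert (sc.n50, sc.l50, sc.ng50, sc.lg50) == (70, 2, 50, 3)
        assert sc.estimated_genome_size == 400
        assert sc.mean_length == 290 / 6
        assert sc.median_length == 45.0  # midpoint of 40 and 50

    def test_gapped_scaffold_contig_decomposition(self):
        rec = SequenceRecord(id="s", seq="ACGT" + "N" * 10 + "ACGT")
        sc, ct = assembly_metrics([rec])
        assert sc.n_scaffolds == 1 and sc.total_bases == 18
        assert sc.n_percent == pytest.approx(100 * 10 / 18)
        assert ct.n_contigs == 2 and ct.n50 == 4
        assert sc.total_contig_bases == 8 == ct.total_bases

    def test_short_n_runs_stay_in_contigs(self):
        rec = SequenceRecord(id="s", seq="ACGTNNNACGT" + "N" * 12 + "GGCC")
        sc, ct = assembly_metrics([rec])
        assert ct.n_contigs == 2
        # short N run is inside the first contig; conservation of bases
        assert sc.total_contig_bases == 11 + 4
        assert ct.n_percent == pytest.approx(100 * 3 / 15)

    def test_invariants_on_random_assemblies(self):
        rng = random.Random(11)
        for _ in range(20):
            recs = [
                SequenceRecord(
                    id=f"s{i}",
                    seq="".join(rng.choice("ACGTN") for _ in range(rng.randint(30, 400))),
                )
                for i in range(rng.randint(1, 10))
            ]
            try:
                sc, ct = assembly_metrics(recs, estimated_genome_size=5000)
            except ValueError:
                continue  # all-gap assembly
            assert ct.n_contigs >= sc.n_scaffolds
            assert sc.shortest_seq <= sc.median_length <= sc.longest_seq
            assert sc.shortest_seq <= sc.mean_length <= sc.longest_seq
            assert sc.l50 >= 1 and sc.n50 <= sc.longest_seq and sc.n90 <= sc.n50
            assert 0 <= sc.gc_percent <= 100 and 0 <= sc.n_percent <= 100

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            assembly_metrics([])
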