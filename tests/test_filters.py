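"""Retention cascade: dereplication, error pruning, prescreen,
translation, replicate consistency."""

import numpy as np
import pandas as pd
import pytest

from edna.filters import (
    dereplicate,
    identity_prescreen,
    prune_errors,
    replicate_filter,
    run_filters,
    translation_filter,
)
from edna.taxonomy import ReferenceRecord


def table_from(columns: dict) -> pd.DataFrame:
    """{(sample, rep): {seq: count}} -> ReplicateTable DataFrame."""
    df = pd.DataFrame(columns).fillna(0).astype(np.int64)
    df.columns = pd.MultiIndex.from_tuples(columns.keys(),
                                           names=["sample", "replicate"])
    return df


def ref(seq, rid="r1", metazoan=True, phylum="Arthropoda"):
    return ReferenceRecord(rid, seq, f"Species {rid}", phylum, metazoan)


class TestDereplicate:
    def test_exact_counts(self):
        t = dereplicate({("S1", 1): ["AAAA", "AAAA", "CCCC"]})
        assert t.loc["AAAA", ("S1", 1)] == 2
        assert t.loc["CCCC", ("S1", 1)] == 1

    def test_empty_replicate_keeps_column(self):
        t = dereplicate({("S1", 1): ["AAAA"], ("S1", 2): []})
        assert ("S1", 2) in t.columns
        assert t[("S1", 2)].sum() == 0

    def test_generator_depth_yields_one_row_per_species(self):
        from edna.seqio import tag_lookup_from_design
        from edna.seqio import demultiplex, trim_primers
        from edna.synth import StudyDesign, generate_species_pool, simulate_reads

        design = StudyDesign(sites_per_habitat=1)
        pool = generate_species_pool(0, 0, 3, 0, seed=2, design=design,
                                     occupancy_prob=1.0)
        reads, _ = simulate_reads(pool, depth_per_replicate=200, seed=2)
        demux = demultiplex(reads, tag_lookup_from_design(design.tag_map))
        bins = {
            key: [trim_primers(r.sequence) for r in rs]
            for key, rs in demux.bins.items()
        }
        t = dereplicate(bins)
        for col in t.columns:
            assert (t[col] > 0).sum() == 3


class TestPruneErrors:
    def test_absorption_hand_trace(self):
        t = table_from({("S1", 1): {"AAAA": 100, "AAAT": 2}})
        out = prune_errors(t, max_edit=1, abundance_ratio=10)
        assert list(out.index) == ["AAAA"]
        assert out.loc["AAAA", ("S1", 1)] == 102

    def test_distant_sequences_untouched(self):
        t = table_from({("S1", 1): {"AAAA": 100, "TTTT": 90}})
        out = prune_errors(t, max_edit=1, abundance_ratio=10)
        assert out.shape[0] == 2

    def test_ratio_unmet_untouched(self):
        t = table_from({("S1", 1): {"AAAA": 10, "AAAT": 9}})
        out = prune_errors(t, max_edit=1, abundance_ratio=10)
        assert out.shape[0] == 2

    def test_conserves_reads_never_adds_rows(self):
        rng = np.random.default_rng(0)
        base = "ACGTACGTACGT"
        seqs = {base: 200}
        for i in range(6):
            mutant = base[:i] + "T" + base[i + 1 :]
            seqs.setdefault(mutant, int(rng.integers(1, 30)))
        t = table_from({("S1", 1): seqs, ("S1", 2): seqs})
        out = prune_errors(t)
        assert out.shape[0] <= t.shape[0]
        assert out.to_numpy().sum() == t.to_numpy().sum()

    def test_invalid_params(self):
        t = table_from({("S1", 1): {"AAAA": 1}})
        with pytest.raises(ValueError):
            prune_errors(t, max_edit=0)
        with pytest.raises(ValueError):
            prune_errors(t, abundance_ratio=1.0)


class TestIdentityPrescreen:
    def test_exact_metazoan_kept(self):
        refs = [ref("ACGT" * 80)]
        out = identity_prescreen(["ACGT" * 80], refs)
        assert out.iloc[0]["keep"] and out.iloc[0]["identity"] == 1.0

    def test_nonmetazoan_besthit_discarded(self):
        seq = "ACGT" * 80
        refs = [ref(seq, "alga", metazoan=False, phylum="Chlorophyta"),
                ref("TGCA" * 80, "bug")]
        out = identity_prescreen([seq], refs)
        assert not out.iloc[0]["keep"]
        assert out.iloc[0]["reason"] == "nonmetazoan_besthit"

    def test_low_identity_discarded_brute_force(self):
        rng = np.random.default_rng(1)
        refs = [ref("".join(rng.choice(list("ACGT"), 100)), f"r{i}")
                for i in range(4)]
        query = "".join(rng.choice(list("ACGT"), 100))
        best = max(
            sum(a == b for a, b in zip(query, r.sequence)) / 100 for r in refs
        )
        assert best < 0.80  # random 100-mers sit near 25% identity
        out = identity_prescreen([query], refs)
        assert out.iloc[0]["reason"] == "identity_lt_80"

    def test_empty_refdb_fails(self):
        with pytest.raises(ValueError):
            identity_prescreen(["ACGT"], [])


class TestTranslationFilter:
    def test_generator_barcode_passes(self, small_pool):
        assert translation_filter(small_pool.species[0].barcode)

    def test_stop_in_every_frame_discarded(self):
        # TAA placed in-frame for frames 0, 1 and 2; TAA is a stop under
        # both mitochondrial codes
        seq = "TAA" + "A" + "TAA" + "A" + "TAA"
        assert not translation_filter(seq)

    def test_aga_kept_by_invertebrate_code(self):
        # AGA is a vertebrate-mitochondrial stop but serine for
        # invertebrates; a frame-0-clean sequence with in-frame AGA passes
        seq = "AGA" * 20
        assert translation_filter(seq)


class TestReplicateFilter:
    def _table(self, reps_present, n=5):
        cols = {("S1", r): {"AAAA": (1 if r in reps_present else 0)}
                for r in range(1, n + 1)}
        return table_from(cols)

    @pytest.mark.parametrize(
        "present,kept",
        [({1, 2, 3}, True), ({1, 2}, False), ({1, 2, 3, 4, 5}, True),
         ({2, 4, 5}, True), (set(), False)],
    )
    def test_three_of_five_rule(self, present, kept):
        out = replicate_filter(self._table(present))
        assert ("AAAA" in out["S1"]) == kept

    def test_wrong_replicate_count_warns(self):
        with pytest.warns(UserWarning, match="replicates"):
            replicate_filter(self._table({1, 2, 3}, n=4))

    def test_min_above_n_rejected(self):
        with pytest.raises(ValueError):
            replicate_filter(self._table({1}), min_replicates=6)


class TestCascade:
    def test_report_conservation_noiseless(self, noiseless_run):
        _, _, _, results = noiseless_run
        report = results["filter_report"]
        assert report.check_conservation()
        # zero false negatives on noiseless input
        for rule, n in report.discarded.items():
            assert n == 0, rule

    def test_chimeras_survive_less_than_true_sequences(self):
        from edna.seqio import demultiplex, tag_lookup_from_design, trim_primers
        from edna.synth import generate_species_pool, simulate_reads

        pool = generate_species_pool(6, 6, 3, 0, seed=13)
        reads, _ = simulate_reads(pool, depth_per_replicate=100,
                                  chimera_rate=0.05, seed=13)
        demux = demultiplex(reads, tag_lookup_from_design(pool.design.tag_map))
        bins = {k: [trim_primers(r.sequence) for r in rs]
                for k, rs in demux.bins.items()}
        table = dereplicate(bins)
        true_seqs = {h for sp in pool.species for h in sp.haplotypes}
        observed_chimeras = set(table.index) - true_seqs
        assert observed_chimeras, "chimera channel produced no uniques"
        _, retained, _ = run_filters(table, pool.reference_records(),
                                     min_identity=0.0)
        union = set().union(*retained.values())
        chim_survival = len(union & observed_chimeras) / len(observed_chimeras)
        true_survival = len(union & true_seqs) / len(true_seqs & set(table.index))
        assert chim_survival < true_survival
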