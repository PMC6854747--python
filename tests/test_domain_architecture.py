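"""Fragment merging, architecture calling and domain extraction."""

import pytest
from hypothesis import given, strategies as st

from hybridtrace.domain_architecture import (
    DomainAnnotation,
    DomainInputError,
    MergeConfig,
    classify_architecture,
    classify_table,
    extract_domain_sequences,
    load_vocabulary,
    merge_domains,
    read_architecture_table,
    read_fasta,
    read_interproscan_tsv,
    write_architecture_table,
)


def ks(start, end):
    return DomainAnnotation("g", "KS", start, end)


def _oracle_merge(intervals, config):
    """Independent merge oracle: restart-from-scratch scan until stable."""
    items = sorted(intervals)
    while True:
        for i in range(len(items) - 1):
            (s1, e1), (s2, e2) = items[i], items[i + 1]
            gap = s2 - e1 - 1
            if gap < 0 or (
                (e1 - s1 + 1) < config.max_fragment_len
                and (e2 - s2 + 1) < config.max_fragment_len
                and gap < config.max_gap
            ):
                items[i] = (s1, max(e1, e2))
                del items[i + 1]
                break
        else:
            return items


class TestMergeDomains:
    def test_close_short_fragments_merge(self):
        merged = merge_domains([ks(1, 200), ks(280, 450)])
        assert [(d.start, d.end) for d in merged] == [(1, 450)]

    def test_long_fragment_blocks_merge(self):
        merged = merge_domains([ks(1, 400), ks(480, 600)])
        assert len(merged) == 2

    def test_chain_merges_to_fixed_point(self):
        merged = merge_domains([ks(1, 100), ks(150, 240), ks(300, 380)])
        assert [(d.start, d.end) for d in merged] == [(1, 380)]

    def test_overlap_merges_unconditionally_with_flag(self):
        merged = merge_domains([ks(1, 400), ks(380, 900)])
        assert [(d.start, d.end) for d in merged] == [(1, 900)]
        assert merged[0].merged_overlap

    def test_different_types_never_merge(self):
        domains = [ks(1, 100), DomainAnnotation("g", "AT", 120, 200)]
        assert len(merge_domains(domains)) == 2

    def test_mixed_gene_ids_rejected(self):
        with pytest.raises(DomainInputError, match="mixed"):
            merge_domains([ks(1, 100), DomainAnnotation("h", "KS", 200, 300)])

    @given(
        st.lists(
            st.tuples(st.integers(1, 2000), st.integers(1, 500)),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_scan_oracle_and_is_idempotent(self, raw):
        domains = [ks(s, s + ln - 1) for s, ln in raw]
        config = MergeConfig()
        merged = merge_domains(domains, config)
        assert [(d.start, d.end) for d in merged] == _oracle_merge(
            [(d.start, d.end) for d in domains], config
        )
        assert merge_domains(merged, config) == merged  # idempotent
        assert len(merged) <= len(domains)
        # total covered span never shrinks
        covered = set()
        for d in domains:
            covered |= set(range(d.start, d.end + 1))
        covered_after = set()
        for d in merged:
            covered_after |= set(range(d.start, d.end + 1))
        assert covered <= covered_after


class TestClassifyArchitecture:
    @pytest.mark.parametrize(
        "types,expected_class,expected_orientation",
        [
            (["KS", "AT", "T", "C", "A", "T"], "PKS-NRPS", "P-type"),
            (["C", "A", "T", "KS", "AT", "T"], "NRPS-PKS", "N-type"),
            (["A", "T", "R"], "NRPS-like", "none"),
            (["KS", "AT", "T"], "PKS", "none"),
            (["C", "A", "T", "TE"], "NRPS", "none"),
            (["KS", "T"], "PKS-like", "none"),
            (["T", "TE"], "other", "none"),
        ],
    )
    def test_rule_table(self, types, expected_class, expected_orientation):
        domains = [
            DomainAnnotation("g", t, 100 * i + 1, 100 * i + 50)
            for i, t in enumerate(types)
        ]
        arch = classify_architecture(domains)
        assert arch.sm_class == expected_class
        assert arch.orientation == expected_orientation
        assert arch.domain_string == "-".join(types)

    def test_empty_domains_are_other(self):
        assert classify_architecture([], gene_id="g").sm_class == "other"

    def test_permutation_stable(self, rng):
        types = ["KS", "AT", "T", "C", "A", "T"]
        domains = [
            DomainAnnotation("g", t, 100 * i + 1, 100 * i + 50)
            for i, t in enumerate(types)
        ]
        ref = classify_architecture(domains)
        for _ in range(5):
            shuffled = [domains[i] for i in rng.permutation(len(domains))]
            assert classify_architecture(shuffled) == ref


class TestExtraction:
    def test_direct_slice(self):
        arch = classify_architecture(
            [DomainAnnotation("g", "A", 2, 5)], gene_id="g"
        )
        seqs = extract_domain_sequences(arch, "MKTAYIAKQR", {"A"})
        assert seqs[0].sequence == "KTAY"
        assert len(seqs[0].sequence) == 5 - 2 + 1

    def test_unwanted_types_give_empty(self):
        arch = classify_architecture(
            [DomainAnnotation("g", t, 100 * i + 1, 100 * i + 5)
             for i, t in enumerate(["C", "A", "T"])]
        )
        assert extract_domain_sequences(arch, "X" * 400, {"KS"}) == []

    def test_repeated_type_gets_ordinals(self):
        arch = classify_architecture(
            [DomainAnnotation("g", "A", 1, 10), DomainAnnotation("g", "A", 50, 60)]
        )
        seqs = extract_domain_sequences(arch, "X" * 100, {"A"})
        assert [s.seq_id for s in seqs] == ["g_A1", "g_A2"]

    def test_domain_past_protein_end_names_gene(self):
        arch = classify_architecture([DomainAnnotation("g", "A", 1, 50)])
        with pytest.raises(DomainInputError, match="g"):
            extract_domain_sequences(arch, "X" * 10, {"A"})


class TestTableIO:
    def test_toy_interproscan_classifies_hybrids(self, toy_paths):
        per_gene = read_interproscan_tsv(toy_paths["domains"])
        archs = {a.gene_id: a for a in classify_table(per_gene)}
        assert len(archs) == 12
        assert archs["nig1_h1"].sm_class == "PKS-NRPS"
        assert archs["fla1_h2"].sm_class == "NRPS-PKS"
        # the fragmented KS rows (1-200, 260-420) merged into one domain
        ks_domains = [
            d for d in archs["nig1_h1"].ordered_domains if d.domain_type == "KS"
        ]
        assert [(d.start, d.end) for d in ks_domains] == [(1, 420)]

    def test_duplicate_type_start_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        row = "g\tmd5\t500\tPfam\tPF00109\td\t1\t200\t0\tT\tx"
        p.write_text(row + "\n" + row + "\n")
        with pytest.raises(DomainInputError, match="duplicate"):
            read_interproscan_tsv(p)

    def test_unmapped_signatures_dropped(self, tmp_path):
        p = tmp_path / "u.tsv"
        p.write_text("g\tmd5\t500\tPfam\tPF99999\td\t1\t200\t0\tT\tx\n")
        assert read_interproscan_tsv(p) == {}

    def test_architecture_table_round_trip(self, toy_paths, tmp_path):
        per_gene = read_interproscan_tsv(toy_paths["domains"])
        archs = classify_table(per_gene)
        p = tmp_path / "arch.tsv"
        write_architecture_table(archs, p)
        assert read_architecture_table(p) == archs

    def test_vocabulary_includes_identity_tokens(self):
        vocab = load_vocabulary()
        assert vocab["PF00109"] == "KS" and vocab["KS"] == "KS"

    def test_extraction_matches_fasta(self, toy_paths):
        per_gene = read_interproscan_tsv(toy_paths["domains"])
        archs = classify_table(per_gene)
        proteins = read_fasta(toy_paths["fasta"])
        arch = next(a for a in archs if a.gene_id == "nig1_h1")
        seqs = extract_domain_sequences(arch, proteins["nig1_h1"], {"KS", "A"})
        assert {s.seq_id for s in seqs} == {"nig1_h1_KS1", "nig1_h1_A1"}
        assert all(len(s.sequence) == s.end - s.start + 1 for s in seqs)
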