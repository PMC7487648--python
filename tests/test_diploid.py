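"""Diploid genome construction, coordinate liftover, annotation merging."""

import numpy as np
import pytest
from oracles import quadratic_merge_oracle, string_edit_oracle

from tuglocus.diploid import (
    CoordinateMap,
    Transcript,
    Variant,
    VariantTable,
    apply_variants,
    lift_annotation,
    merge_annotations,
)


def _tx(tid, exons, chrom="chr1", strand="+", biotype="protein_coding"):
    return Transcript(tid, tid, chrom, strand, tuple(exons), biotype)


def _random_variants(rng, seq, n, lo=0, hi=None, snp_only=False):
    hi = hi if hi is not None else len(seq) - 5
    positions = sorted(rng.choice(np.arange(lo, hi), size=n, replace=False))
    variants = []
    last_end = -1
    for pos in positions:
        pos = int(pos)
        if pos <= last_end:
            continue
        kind = 0 if snp_only else int(rng.integers(0, 3))
        if kind == 0:  # SNP
            alt = rng.choice([b for b in "ACGT" if b != seq[pos]])
            variants.append(Variant("chr1", pos, seq[pos], str(alt), "CAST"))
            last_end = pos
        elif kind == 1:  # insertion
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            variants.append(Variant("chr1", pos, seq[pos], seq[pos] + ins, "CAST"))
            last_end = pos
        else:  # deletion (1-3 bases after the anchor)
            k = int(rng.integers(1, 4))
            variants.append(
                Variant("chr1", pos, seq[pos : pos + 1 + k], seq[pos], "CAST")
            )
            last_end = pos + k
    return variants


class TestApplyVariants:
    def test_empty_table_is_identity(self):
        ref = {"chr1": "ACGTACGTAC"}
        out, cmap = apply_variants(ref, VariantTable([]), "CAST")
        assert out == ref
        assert cmap.blocks["chr1"] == [(0, 10, 0)]
        assert cmap.map_position("chr1", 7) == 7

    def test_insertion_shifts_downstream_positions(self):
        ref = {"chr1": "AAAACCCCGGGG"}
        table = VariantTable([Variant("chr1", 3, "A", "ATT", "CAST")], ref)
        out, cmap = apply_variants(ref, table, "CAST")
        assert out["chr1"] == "AAAATTCCCCGGGG"
        for p in range(0, 4):
            assert cmap.map_position("chr1", p) == p
        for p in range(4, 12):
            assert cmap.map_position("chr1", p) == p + 2

    def test_matches_string_edit_oracle_on_random_variants(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        variants = _random_variants(rng, seq, 100)
        table = VariantTable(variants, {"chr1": seq})
        out, _ = apply_variants({"chr1": seq}, table, "CAST")
        assert out["chr1"] == string_edit_oracle(seq, variants)

    def test_length_change_equals_net_indel_length(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        variants = _random_variants(rng, seq, 60)
        net = sum(len(v.alt) - len(v.ref) for v in variants)
        out, _ = apply_variants({"chr1": seq}, VariantTable(variants), "CAST")
        assert len(out["chr1"]) - len(seq) == net

    def test_unedited_intervals_conserved(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        variants = _random_variants(rng, seq, 20, lo=500, hi=1500)
        out, cmap = apply_variants({"chr1": seq}, VariantTable(variants), "CAST")
        a, b = cmap.map_interval("chr1", 0, 400)
        assert out["chr1"][a:b] == seq[0:400]
        a, b = cmap.map_interval("chr1", 1600, 2000)
        assert out["chr1"][a:b] == seq[1600:2000]

    def test_ref_mismatch_error_names_position(self):
        ref = {"chr1": "ACGT"}
        with pytest.raises(ValueError, match="chr1:3"):
            apply_variants(ref, VariantTable([Variant("chr1", 2, "T", "A", "CAST")]), "CAST")

    def test_zero_length_reference_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            apply_variants({"chr1": ""}, VariantTable([]), "CAST")

    def test_overlapping_variants_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            VariantTable(
                [
                    Variant("chr1", 2, "GTA", "G", "CAST"),
                    Variant("chr1", 3, "T", "C", "CAST"),
                ]
            )


class TestCoordinateMap:
    def test_monotone_and_roundtrip(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        variants = _random_variants(rng, seq, 40)
        _, cmap = apply_variants({"chr1": seq}, VariantTable(variants), "CAST")
        inv = cmap.inverse()
        mapped = [(p, cmap.map_position("chr1", p)) for p in range(len(seq))]
        kept = [(p, m) for p, m in mapped if m is not None]
        # monotone
        ms = [m for _, m in kept]
        assert all(a < b for a, b in zip(ms, ms[1:]))
        # round-trip for positions outside deleted bases
        for p, m in kept[::37]:
            assert inv.map_position("chr1", m) == p

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            CoordinateMap({"chr1": [(0, 10, 0)]}).map_position("chrX", 1)


class TestLiftAnnotation:
    def test_identity_map_preserves_annotation(self):
        tx = _tx("t1", [(10, 50), (100, 200)])
        cmap = CoordinateMap.identity({"chr1": 300})
        assert lift_annotation([tx], cmap) == [tx]

    def test_exon_downstream_of_deletion_shifts(self):
        ref = {"chr1": "A" * 500}
        table = VariantTable([Variant("chr1", 10, "AAAA", "A", "CAST")], ref)
        _, cmap = apply_variants(ref, table, "CAST")
        [lifted] = lift_annotation([_tx("t1", [(100, 200)])], cmap)
        assert lifted.exons == ((97, 197),)

    def test_transcript_with_boundary_in_deletion_dropped(self, caplog):
        ref = {"chr1": "A" * 100}
        table = VariantTable([Variant("chr1", 48, "AAAA", "A", "CAST")], ref)
        _, cmap = apply_variants(ref, table, "CAST")
        out = lift_annotation([_tx("t1", [(50, 80)])], cmap)
        assert out == []

    def test_lifted_sequences_match_per_transcript_edit_oracle(self, rng):
        # variants confined to exon interiors so the per-transcript oracle
        # (edit the spliced sequence in transcript coordinates) is exact
        seq = "".join(rng.choice(list("ACGT"), size=6_000))
        exons = [(500, 1500), (2500, 3500), (4500, 5500)]
        tx = _tx("t1", exons)
        variants = []
        for s, e in exons:
            variants += _random_variants(rng, seq, 15, lo=s + 10, hi=e - 10)
        variants += _random_variants(rng, seq, 5, lo=1600, hi=2400)  # intronic
        variants = sorted(variants, key=lambda v: v.pos)
        table = VariantTable(variants, {"chr1": seq})
        genome2, cmap = apply_variants({"chr1": seq}, table, "CAST")
        [lifted] = lift_annotation([tx], cmap)
        got = lifted.sequence(genome2)

        # oracle: splice the reference transcript, then apply exonic variants
        # with coordinates mapped into transcript space
        spliced = tx.sequence({"chr1": seq})
        tx_vars = []
        offset = 0
        for s, e in exons:
            for v in variants:
                if s <= v.pos and v.pos + len(v.ref) <= e:
                    tx_vars.append(
                        Variant("t1", v.pos - s + offset, v.ref, v.alt, v.strain)
                    )
            offset += e - s
        assert got == string_edit_oracle(spliced, tx_vars)


class TestMergeAnnotations:
    def test_duplicate_additions_collapse_to_primary(self):
        primary = [_tx("a", [(0, 100)]), _tx("b", [(200, 300)])]
        merged = merge_annotations(primary, [list(primary)], set())
        assert merged == primary

    def test_excluded_biotype_removed(self):
        primary = [_tx("a", [(0, 100)]), _tx("mir", [(500, 600)], biotype="miRNA")]
        merged = merge_annotations(primary, [], {"miRNA"})
        assert [t.transcript_id for t in merged] == ["a"]

    def test_opposite_strand_overlap_is_allowed(self):
        primary = [_tx("a", [(0, 100)])]
        addition = [_tx("b", [(50, 150)], strand="-")]
        merged = merge_annotations(primary, [addition], set())
        assert len(merged) == 2

    def test_matches_quadratic_overlap_oracle(self, rng):
        def random_set(n, tag):
            out = []
            for i in range(n):
                start = int(rng.integers(0, 5_000))
                n_ex = int(rng.integers(1, 4))
                exons = []
                p = start
                for _ in range(n_ex):
                    ln = int(rng.integers(50, 300))
                    exons.append((p, p + ln))
                    p += ln + int(rng.integers(50, 300))
                strand = "+" if rng.random() < 0.5 else "-"
                bt = "miRNA" if rng.random() < 0.2 else "protein_coding"
                out.append(_tx(f"{tag}{i}", exons, strand=strand, biotype=bt))
            return out

        for trial in range(5):
            primary = random_set(8, f"p{trial}_")
            additions = [random_set(6, f"x{trial}_"), random_set(6, f"y{trial}_")]
            got = merge_annotations(primary, additions, {"miRNA"})
            expected = quadratic_merge_oracle(primary, additions, {"miRNA"})
            assert [t.transcript_id for t in got] == [t.transcript_id for t in expected]

    def test_idempotent(self, rng):
        primary = [_tx("a", [(0, 100)]), _tx("b", [(50, 150)]), _tx("c", [(400, 500)])]
        merged = merge_annotations(primary, [], set())
        again = merge_annotations(merged, [list(merged)], set())
        assert again == merged
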