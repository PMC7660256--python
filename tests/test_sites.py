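"""Context typing, regulon-size bounds and the site report table."""

import pytest
from hypothesis import given, strategies as st

from regulonscan import (
    BindingPeak,
    GeneFeature,
    GenomeAnnotation,
    GenomicContext,
    RegulonEstimate,
    SiteType,
    TypedSite,
    assemble_site_table,
    build_fixture_annotation,
    classify_site,
    classify_sites,
    estimate_regulon_size,
    fixture_peaks,
    scan_window,
)


def annotation_for(left_strand, right_strand):
    return GenomeAnnotation(
        genome_length=2000,
        features=(
            GeneFeature(id="gl", start=100, end=400, strand=left_strand),
            GeneFeature(id="gr", start=600, end=900, strand=right_strand),
        ),
    )


def peak(position, hi=1000.0, lo=None):
    return BindingPeak(position=position, intensity_no_effector=hi,
                       intensity_effector=lo)


class TestClassifySite:
    def test_divergent_spacer_is_type_a_with_two_targets(self):
        # mirrors the aroP< >pdhR configuration around peak 122052's spacer
        site = classify_site(peak(500), annotation_for("-", "+"))
        assert site.site_type is SiteType.A
        assert {g.id for g in site.regulated_genes} == {"gl", "gr"}

    def test_tandem_spacer_is_type_b_upstream_gene_only(self):
        # mirrors mngB> >cydA: upstream of the downstream-plus gene only
        site = classify_site(peak(500), annotation_for("+", "+"))
        assert site.site_type is SiteType.B
        assert [g.id for g in site.regulated_genes] == ["gr"]

    def test_tandem_minus_pair_regulates_left_gene(self):
        site = classify_site(peak(500), annotation_for("-", "-"))
        assert site.site_type is SiteType.B
        assert [g.id for g in site.regulated_genes] == ["gl"]

    def test_convergent_spacer_is_type_c_with_no_targets(self):
        site = classify_site(peak(500), annotation_for("+", "-"))
        assert site.site_type is SiteType.C
        assert site.regulated_genes == ()

    def test_position_inside_orf_is_type_d(self):
        site = classify_site(peak(250), annotation_for("+", "+"))
        assert site.site_type is SiteType.D
        assert site.context.host_gene.id == "gl"

    def test_k12_like_peak_inside_ftsI_is_type_d(self):
        ann = build_fixture_annotation()
        site = classify_site(peak(92666), ann)
        assert site.site_type is SiteType.D
        assert site.context.host_gene.id == "ftsI"

    def test_max_upstream_distance_demotes_distant_site(self):
        site = classify_site(peak(500), annotation_for("-", "+"),
                             max_upstream_distance=50)
        assert site.site_type is SiteType.C

    def test_missing_flank_classified_from_remaining_side(self, caplog):
        ann = GenomeAnnotation(
            genome_length=2000,
            features=(GeneFeature(id="g", start=600, end=900, strand="+"),),
        )
        with caplog.at_level("WARNING"):
            site = classify_site(peak(100), ann)
        assert site.site_type is SiteType.B
        assert "no flanking gene" in caplog.text

    def test_mirror_reflection_preserves_types(self):
        L = 2000
        for strands, expected in ((("-", "+"), SiteType.A),
                                  (("+", "+"), SiteType.B),
                                  (("+", "-"), SiteType.C)):
            ann = annotation_for(*strands)
            mirrored = GenomeAnnotation(
                genome_length=L,
                features=tuple(
                    GeneFeature(id=f.id, start=L + 1 - f.end, end=L + 1 - f.start,
                                strand="-" if f.strand == "+" else "+")
                    for f in ann
                ),
            )
            assert classify_site(peak(500), ann).site_type is expected
            assert classify_site(peak(L + 1 - 500), mirrored).site_type is expected


class TestFixtureTyping:
    def test_packaged_table_reproduces_published_type_counts(self):
        typed = classify_sites(fixture_peaks(), build_fixture_annotation())
        est = estimate_regulon_size(typed)
        assert (est.n_typeA, est.n_typeB, est.n_typeC, est.n_typeD) == (7, 9, 0, 19)

    def test_type_partition_covers_all_input_peaks(self):
        peaks = fixture_peaks()
        est = estimate_regulon_size(
            classify_sites(peaks, build_fixture_annotation())
        )
        assert est.total_sites == len(peaks)


class TestRegulonEstimate:
    def test_published_counts_give_16_to_23_targets(self):
        est = RegulonEstimate(n_typeA=7, n_typeB=9, n_typeC=0, n_typeD=19)
        assert (est.min_targets, est.max_targets) == (16, 23)

    def test_no_sites_gives_zero_bounds(self):
        est = estimate_regulon_size([])
        assert (est.min_targets, est.max_targets) == (0, 0)

    def test_small_mixed_collection(self):
        est = RegulonEstimate(n_typeA=3, n_typeB=2, n_typeC=0, n_typeD=0)
        assert (est.min_targets, est.max_targets) == (5, 8)

    @given(
        n_a=st.integers(min_value=0, max_value=50),
        n_b=st.integers(min_value=0, max_value=50),
        n_c=st.integers(min_value=0, max_value=50),
        n_d=st.integers(min_value=0, max_value=50),
    )
    def test_bound_gap_equals_divergent_count(self, n_a, n_b, n_c, n_d):
        est = RegulonEstimate(n_typeA=n_a, n_typeB=n_b, n_typeC=n_c, n_typeD=n_d)
        assert est.min_targets <= est.max_targets
        assert est.max_targets - est.min_targets == est.n_typeA


class TestAssembleSiteTable:
    def test_perfect_site_row_renders_sequence_score_and_position(self):
        ann = build_fixture_annotation()
        p = peak(121966, 9889.0, 9234.0)
        typed = classify_sites([p], ann)
        window = "C" * 69 + "AATTGGTAAGACCAATT" + "G" * 69
        match = scan_window(window, origin=121983)
        table = assemble_site_table(typed, {121966: match})
        row = table.iloc[0]
        assert row.site_sequence == "AATTGGTaagACCAATT"
        assert row.conservation == "14/14"
        assert row.motif_position == 122052
        assert row.site_type == "A"
        assert row.regulated_genes == "aroP,pdhR"
        assert (row.left_arrow, row.right_arrow) == ("<", ">")

    def test_match_below_reporting_floor_renders_dash(self):
        typed = classify_sites([peak(500)], annotation_for("-", "+"))
        weak = scan_window("CCCCCCCAAAGGGGGGG", origin=1)
        table = assemble_site_table(typed, {500: weak}, reporting_floor=7)
        assert list(table[["site_sequence", "conservation", "motif_position"]]
                    .iloc[0]) == ["-", "-", "-"]

    def test_absent_match_renders_dash(self):
        typed = classify_sites([peak(500)], annotation_for("-", "+"))
        table = assemble_site_table(typed, {})
        assert table.iloc[0].site_sequence == "-"

    def test_empty_input_gives_header_only_table(self):
        table = assemble_site_table([])
        assert len(table) == 0
        assert "conservation" in table.columns

    def test_duplicate_peak_identity_is_error(self):
        typed = classify_sites([peak(500), peak(500)], annotation_for("-", "+"))
        with pytest.raises(ValueError, match="duplicate"):
            assemble_site_table(typed)


class TestTypedSiteInvariants:
    def test_type_a_requires_two_regulated_genes(self):
        ctx = GenomicContext(kind="intergenic")
        with pytest.raises(ValueError, match="regulated genes"):
            TypedSite(peak=peak(1), site_type=SiteType.A, context=ctx,
                      regulated_genes=())

    def test_type_d_rejects_regulated_genes(self):
        g = GeneFeature(id="g", start=1, end=10, strand="+")
        ctx = GenomicContext(kind="intragenic", host_gene=g)
        with pytest.raises(ValueError, match="regulated genes"):
            TypedSite(peak=peak(5), site_type=SiteType.D, context=ctx,
                      regulated_genes=(g,))
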