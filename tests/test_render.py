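"""Renderer: stain styles, scene composition, PNG/SVG backends, determinism."""

import io
import xml.dom.minidom

import pytest
from PIL import Image

from ideoplot import (
    PlotConfig,
    Stain,
    UsageError,
    build_scene,
    parse_input,
    render,
    stain_to_style,
)
from ideoplot.render import TRANS_ALPHA
from ideoplot.scene import scene_bbox


def tagged(cmds, tag):
    return [c for c in cmds if c.tag == tag]


def grey(color):
    assert color.r == color.g == color.b
    return color.r


class TestStainStyle:
    def test_gneg_is_white(self):
        assert stain_to_style(Stain.GNEG).rgb == (255, 255, 255)

    def test_grey_ramp_strictly_darkens(self):
        ramp = [
            grey(stain_to_style(s))
            for s in (Stain.GNEG, Stain.GPOS25, Stain.GPOS50, Stain.GPOS75, Stain.GPOS100)
        ]
        assert ramp == sorted(ramp, reverse=True)
        assert len(set(ramp)) == 5

    def test_heterochromatin_dark_blue_stalk_light_blue(self):
        acen, gvar, stalk = (
            stain_to_style(s) for s in (Stain.ACEN, Stain.GVAR, Stain.STALK)
        )
        assert acen == gvar
        assert acen.b > acen.r and acen.b > acen.g  # blue-dominant
        assert stalk.b > stalk.r
        assert sum(stalk.rgb) > sum(acen.rgb)  # lighter


@pytest.fixture
def simple_input():
    return parse_input(
        "CHR\tPOS\tEND\tPHENOTYPE\tNOTE\n"
        "1\t100000\t\tA\tMHC\n"
        "1\t600000\t700000\t\t\n"
        "2\t250000\t\tB\tlongnotetext\n"
    )


class TestScene:
    def test_one_mark_per_record(self, simple_input, tiny_genome):
        cmds, _, _ = build_scene(simple_input, tiny_genome, PlotConfig())
        assert len(tagged(cmds, "mark-line")) == 2   # two point records
        assert len(tagged(cmds, "mark-region")) == 1  # one END span

    def test_one_glyph_per_phenotype_record(self, simple_input, tiny_genome):
        cmds, _, _ = build_scene(simple_input, tiny_genome, PlotConfig())
        assert len(tagged(cmds, "glyph")) == 2
        assert len(tagged(cmds, "connector")) == 2

    def test_band_fills_gated_by_shading_flag(self, simple_input, tiny_genome):
        off, _, _ = build_scene(simple_input, tiny_genome, PlotConfig())
        on, _, _ = build_scene(
            simple_input, tiny_genome, PlotConfig(shade_chromatin=True)
        )
        assert len(tagged(off, "band")) == 0
        n_bands = sum(len(b) for b in tiny_genome.bands.values())
        assert len(tagged(on, "band")) == n_bands

    def test_thick_boundary_doubles_stroke(self, simple_input, tiny_genome):
        thin, _, _ = build_scene(simple_input, tiny_genome, PlotConfig())
        thick, _, _ = build_scene(
            simple_input, tiny_genome, PlotConfig(thick_boundary=True)
        )
        w_thin = tagged(thin, "chrom-outline")[0].stroke_w
        w_thick = tagged(thick, "chrom-outline")[0].stroke_w
        assert w_thick == pytest.approx(2 * w_thin)

    def test_outline_flag_strokes_every_glyph(self, simple_input, tiny_genome):
        plain, _, _ = build_scene(simple_input, tiny_genome, PlotConfig())
        outlined, _, _ = build_scene(
            simple_input, tiny_genome, PlotConfig(outline_circle=True)
        )
        assert all(g.stroke is None for g in tagged(plain, "glyph"))
        assert all(g.stroke is not None for g in tagged(outlined, "glyph"))

    def test_small_circle_halves_diameter(self, simple_input, tiny_genome):
        big, gb, _ = build_scene(simple_input, tiny_genome, PlotConfig())
        small, gs, _ = build_scene(
            simple_input, tiny_genome, PlotConfig(small_circle=True)
        )
        assert gs.glyph_d_px == pytest.approx(gb.glyph_d_px / 2)

    def test_annotation_gated_and_truncated(self, simple_input, tiny_genome):
        off, _, _ = build_scene(simple_input, tiny_genome, PlotConfig())
        on, _, _ = build_scene(
            simple_input, tiny_genome, PlotConfig(include_annotation=True)
        )
        assert tagged(off, "annotation") == []
        notes = {t.text for t in tagged(on, "annotation")}
        assert notes == {"MHC", "longnotete"}

    def test_annotation_right_of_chromosome(self, simple_input, tiny_genome):
        cmds, geom, _ = build_scene(
            simple_input, tiny_genome, PlotConfig(include_annotation=True)
        )
        for note in tagged(cmds, "annotation"):
            track = next(
                t for t in geom.tracks.values()
                if t.y_top_px - 20 <= note.y <= t.y_bottom_px + 20
            )
            assert note.x > track.x_right_px

    def test_trans_lines_alpha(self, simple_input, tiny_genome):
        cmds, _, _ = build_scene(
            simple_input, tiny_genome, PlotConfig(trans_lines=True)
        )
        assert all(
            c.stroke.alpha == pytest.approx(TRANS_ALPHA)
            for c in tagged(cmds, "mark-line")
        )

    def test_thin_lines_halve_width(self, simple_input, tiny_genome):
        normal, _, _ = build_scene(simple_input, tiny_genome, PlotConfig())
        thin, _, _ = build_scene(simple_input, tiny_genome, PlotConfig(thin_lines=True))
        w_n = tagged(normal, "mark-line")[0].stroke_w
        w_t = tagged(thin, "mark-line")[0].stroke_w
        assert w_t == pytest.approx(w_n / 2)

    def test_legend_one_entry_per_phenotype(self, gwas_like_input, hg19):
        cmds, _, _ = build_scene(gwas_like_input, hg19, PlotConfig())
        assert len(tagged(cmds, "legend-swatch")) == 8
        labels = [t.text for t in tagged(cmds, "legend-label")]
        assert labels == gwas_like_input.phenotypes  # legend order = first seen

    def test_no_phenotypes_no_legend(self, tiny_genome):
        parsed = parse_input("CHR\tPOS\n1\t100\n")
        cmds, _, _ = build_scene(parsed, tiny_genome, PlotConfig())
        assert tagged(cmds, "legend-swatch") == []

    def test_big_font_scales_legend_labels(self, gwas_like_input, hg19):
        normal, _, _ = build_scene(gwas_like_input, hg19, PlotConfig())
        big, _, _ = build_scene(gwas_like_input, hg19, PlotConfig(big_font=True))
        assert (
            tagged(big, "legend-label")[0].font_px
            > tagged(normal, "legend-label")[0].font_px
        )

    def test_ancestry_shapes_add_legend_key(self, tiny_genome):
        parsed = parse_input(
            "CHR\tPOS\tPHENOTYPE\tETHNICITY\n"
            "1\t100\tA\tEUR\n1\t200000\tA\tAFR\n2\t300000\tB\tEAS\n"
        )
        cmds, _, _ = build_scene(parsed, tiny_genome, PlotConfig())
        assert len(tagged(cmds, "legend-shape")) == 3
        glyph_types = {type(g).__name__ for g in tagged(cmds, "glyph")}
        assert glyph_types == {"CircleCmd", "RectCmd", "PolygonCmd"}

    def test_zoom_excludes_outside_records_with_warning(self, tiny_genome):
        parsed = parse_input("CHR\tPOS\tPHENOTYPE\n1\t100\tA\n1\t900000\tA\n")
        config = PlotConfig(zoom=__import__("ideoplot").parse_zoom("1:1-500000"))
        cmds, _, warnings = build_scene(parsed, tiny_genome, config)
        assert len(tagged(cmds, "glyph")) == 1
        assert any("outside the zoom region" in w for w in warnings)

    def test_commands_within_canvas(self, gwas_like_input, hg19):
        cmds, geom, _ = build_scene(
            gwas_like_input, hg19, PlotConfig(include_annotation=True, title="t")
        )
        x0, y0, x1, y1 = scene_bbox(cmds)
        assert x0 >= 0 and y0 >= 0
        assert x1 <= geom.width_px and y1 <= geom.height_px


class TestBackends:
    def test_png_decodes_with_dpi_metadata(self, simple_input, tiny_genome):
        image, _ = render(simple_input, tiny_genome, PlotConfig())
        decoded = Image.open(io.BytesIO(image.payload))
        assert decoded.format == "PNG"
        assert decoded.size == (image.width_px, image.height_px)
        assert round(decoded.info["dpi"][0]) == 300

    def test_high_res_sets_1200_dpi(self, simple_input, tiny_genome):
        image, _ = render(simple_input, tiny_genome, PlotConfig(high_res=True))
        decoded = Image.open(io.BytesIO(image.payload))
        assert round(decoded.info["dpi"][0]) == 1200
        assert image.dpi == 1200

    def test_svg_is_well_formed_xml(self, simple_input, tiny_genome):
        image, _ = render(simple_input, tiny_genome, PlotConfig(out_format="svg"))
        doc = xml.dom.minidom.parseString(image.payload)
        assert doc.documentElement.tagName == "svg"

    def test_unsupported_format_rejected(self):
        with pytest.raises(UsageError, match="unsupported output format"):
            PlotConfig(out_format="pdf")

    def test_byte_determinism(self, simple_input, tiny_genome):
        config = PlotConfig(title="t", include_annotation=True, seed=7)
        a, _ = render(simple_input, tiny_genome, config)
        b, _ = render(simple_input, tiny_genome, config)
        assert a.payload == b.payload
        sa, _ = render(simple_input, tiny_genome, PlotConfig(out_format="svg"))
        sb, _ = render(simple_input, tiny_genome, PlotConfig(out_format="svg"))
        assert sa.payload == sb.payload

    def test_empty_record_list_renders_bare_ideograms(self, tiny_genome):
        parsed = parse_input("CHR\tPOS\n")
        image, warnings = render(parsed, tiny_genome, PlotConfig())
        assert warnings == []
        Image.open(io.BytesIO(image.payload)).verify()

    def test_stacked_translucent_marks_composite(self, tiny_genome):
        # two identical 0.4-alpha black lines leave 1-(1-.4)^2 = 0.64 coverage,
        # darkening white toward 255*0.36 ≈ 92 at the overlap
        parsed = parse_input("CHR\tPOS\n1\t500000\n1\t500000\n")
        one = parse_input("CHR\tPOS\n1\t500000\n")
        cfg = PlotConfig(trans_lines=True)
        img2, _ = render(parsed, tiny_genome, cfg)
        img1, _ = render(one, tiny_genome, cfg)
        cmds, geom, _ = build_scene(parsed, tiny_genome, cfg)
        mark = next(c for c in cmds if c.tag == "mark-line")
        x = int((mark.x1 + mark.x2) / 2)
        y = int(round(mark.y1))
        px2 = Image.open(io.BytesIO(img2.payload)).getpixel((x, y))[0]
        px1 = Image.open(io.BytesIO(img1.payload)).getpixel((x, y))[0]
        assert px1 == pytest.approx(255 * 0.6, abs=4)
        assert px2 == pytest.approx(255 * 0.36, abs=4)
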