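# ideoplot

Annotated chromosome ideograms from a single tab-delimited file.

An ideogram is an idealized schematic of a chromosome — its size, centromere
constriction, and optionally its Giemsa banding pattern. Overlaying genomic
results on ideograms gives a whole-genome view of where things happen:
GWAS/PheWAS hits as colored circles tethered to their base-pair positions,
genotyping-array coverage as transverse lines whose density reads directly
off the figure, CNV calls as filled regions layered in color. `ideoplot`
renders all of these, as a Python library and a small command-line tool, for
anyone who has a table of `(chromosome, position[, attributes])` rows and
wants a publication-ready karyogram figure (PNG with physical-resolution
metadata, or SVG).

## What it draws, and how

**Input.** One TSV with recognized headers `CHR` and `POS` (required) plus
optional `END` (region end), `PHENOTYPE`, `NOTE`/`ANNOTATION` (≤10 chars),
`ETHNICITY`/`ANCESTRY`, `GROUP`, and `POSCOLOR` (integer 0–7 selecting the
transverse-mark color). Headers are case-insensitive; invalid rows are fatal
errors that name the offending line.

**Genome.** A bundled human assembly at hg19 scale (24 chromosomes with
centromeres, acrocentric stalks, heterochromatin blocks and grey-band
shading), any user-supplied UCSC-format `cytoBand.txt` file (optionally
gzipped), or a seeded synthetic genome for testing.

**Glyph spacing.** Circles crowd at dense loci, so three placement
algorithms are offered for the vertical positions *y* of glyph runs with
anchors *a₁ ≤ … ≤ aₙ* and diameter *d*:

- `standard` (default): a greedy top-to-bottom sweep, `yᵢ = max(aᵢ, yᵢ₋₁ + d)`,
  with a final push-back pass at the track bottom;
- `equal`: runs at equal intervals, `yᵢ = extent·i/(n+1)`, genomic order kept;
- `proximity`: the exact minimizer of `Σ (yᵢ − aᵢ)²` subject to
  `yᵢ₊₁ − yᵢ ≥ d`, computed by pool-adjacent-violators on the gap-shifted
  anchors (overlapping neighbors merge into clusters centered on their mean
  anchor).

**Colors.** Five phenotype palettes: a fixed 10-color colorblind-aware
`list`; a `generator` spacing hues 360°/n apart in HSV (S=0.78, V=0.90); a
seeded draw without replacement from the 216 `web`-safe colors; seeded
uniform `random` RGB; and `group`, which gives each GROUP a base hue and its
members a lightness gradient. Up to three ancestry groups render as circle,
square and triangle; later groups fall back to the circle. All randomness
flows from one seed (default 7).

**Cytogenetics.** With band shading on, Giemsa-positive bands render in
greys of increasing darkness, Giemsa-negative bands in white,
centromeric/variable heterochromatin in dark blue, and the ribosomal-RNA
stalks of the acrocentric p-arms in light blue.

## Worked example

```python
import ideoplot as ip

genome = ip.builtin_genome()
spec = ip.SyntheticStudySpec(
    n_records=40,
    phenotype_labels=["Crohn's disease", "breast cancer", "blood pressure"],
    note_fraction=0.15,
    seed=7,
)
parsed = ip.parse_input(ip.generate_synthetic_input(spec, genome))
print(f"records: {len(parsed.records)}")
print(f"phenotypes: {parsed.phenotypes}")

colors = ip.assign_colors(parsed.phenotypes, "list")
for p in colors.legend_order:
    print(f"  {p:18s} -> {colors.mapping[p].hex}")

image, warnings = ip.render(
    parsed, genome, ip.PlotConfig(title="Example study", outline_circle=True)
)
print(f"image: {image.width_px}x{image.height_px} px, {image.dpi} DPI, "
      f"{len(image.payload)} bytes ({image.format})")
```

prints

```
records: 40
phenotypes: ["Crohn's disease", 'breast cancer', 'blood pressure']
  Crohn's disease    -> #e6194b
  breast cancer      -> #006ee6
  blood pressure     -> #3cb44b
image: 1080x780 px, 300 DPI, 19120 bytes (png)
```

— 40 synthetic association records across the genome, the three phenotypes
in first-appearance (legend) order with their fixed list-palette colors,
and the encoded whole-genome figure: 24 ideogram tracks in two rows,
connector lines to outlined phenotype circles, and a three-entry legend.

The same figure from the shell:

```sh
ideoplot -i study.tsv -o study.png -t "Example study" -O
ideoplot -i study.tsv -o zoom.png -Z 6:25000000-35000000 -T -n   # zoomed, thin translucent lines
ideoplot -i study.tsv -o bands.png -x -B                         # cytogenetic shading, thick outline
```

Exit status is 0 on success, 1 for data errors (with the input line named),
2 for usage errors.

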