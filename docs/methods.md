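# Methods

## Scope and model

`hpglyco` models the downstream analysis of a site-specific glycopeptide
quantification experiment. The unit of quantification is the glyco-compound:
a glycosite label plus a glycan composition over the four-monomer alphabet
HexNAc / Hex / Fuc / NeuAc. Compositions carry no linkage information, so
several structural isomers may share one row; conversely one precursor m/z
may be consistent with several compositions (see *Isobaric ambiguity*).

Monoisotopic residue masses (monosaccharide minus glycosidic water):
Hex 162.05282, HexNAc 203.07937, Fuc 146.05791, NeuAc 291.09542 Da;
proton 1.007276, water 18.010565, ¹³C isotope spacing 1.003355 Da.
These standard values reproduce the field's diagnostic anchors: the
core-fucose oxonium Hex+HexNAc+Fuc+H⁺ at m/z 512.20, the NeuAc−H₂O oxonium
at 274.092, and the 2×Fuc − 1×NeuAc gap of 1.02 Da.

### Glycan classification

Classification is total and deterministic on composition counts:

* **high-mannose**: HexNAc(2)Hex(5–9) with no Fuc/NeuAc (the Man5–Man9
  series); HexNAc(2) with fewer hexoses falls into paucimannose/other.
* **complex**: HexNAc ≥ 4. Antennarity = min(HexNAc−2, Hex−3), capped at 4
  (two core GlcNAc and three core mannoses are structural; each antenna
  contributes one GlcNAc and, when galactosylated, one hexose). The
  bisecting flag fires when HexNAc−2 > Hex−3 — a HexNAc that no galactose
  accounts for.
* **hybrid**: HexNAc = 3 with Hex ≥ 5; everything else paucimannose/other.

The antennarity/bisecting rule is a *heuristic over compositions*: an
agalactosylated antenna is indistinguishable from a bisecting GlcNAc at this
level, so complex calls carry a `heuristic` marker. The rule was chosen
because it reproduces the canonical labelled series (biantennary
HexNAc(4)Hex(5), bisected biantennary HexNAc(5)Hex(5), tetra-antennary
HexNAc(6)Hex(7)); whether a bisected tri-antennary glycan should count as
tetra-antennary is genuinely open, and this implementation counts it by the
min() rule (i.e. it does not).

### Isobaric ambiguity

Two fucoses outweigh one sialic acid by 1.0204 Da — within ~0.02 Da of one
¹³C spacing — so a monoisotopic-peak misassignment of ±1 isotope makes
Fuc(k+2)NeuAc(m) and Fuc(k)NeuAc(m+1) indistinguishable by precursor mass.
The ambiguity search enumerates count perturbations within a configurable
radius (default 2 per monomer, which covers the swap) and retains candidates
whose residue-mass delta matches k × 1.003355 Da for an allowed k (default
k ∈ {−1, 0, +1}), within a ppm tolerance (default 20 ppm, the conventional
MS2 tolerance) of the intact glycopeptide mass. The search is symmetric:
membership with delta d and isotope k implies the mirrored membership with
−d and −k. Resolution between alternatives is evidential, via diagnostic
ions: core fucose (oxonium 512.20), antennary fucose (the Y-type
peptide+2HexNAc+Fuc+H⁺ ion — peptide-dependent, so never hard-coded), and
sialic acid (292.10 / 274.09).

## Digestion

Trypsin (cleaves after K/R, blocked by following P) plus Glu-C. Glu-C
specificity defaults to E only; the D+E variant is available because Glu-C
cleaves after D in some buffers — the choice is surfaced in the CLI and
report header. Digestion is fully specific with ≤ 2 missed cleavages by
default; cut sites are the union over proteases. Coordinates are 0-based
half-open internally, 1-based in labels, with a configurable numbering
offset so a mature-chain FASTA can carry precursor-style labels (N184 etc.).
Peptide masses use standard amino-acid monoisotopic residues with
carbamidomethyl cysteine (+57.02146 Da) fixed; methionine oxidation
(+15.99491 Da) is available but off by default, since quantification
operates on upstream search-engine output.

## Quantification pipeline

Order is fixed: **normalize → impute → aggregate**.

* **Normalization.** T(s) = sum of the three heavy-standard peptides with
  the highest global mean abundance (ties broken lexicographically; rows
  with any missing value are ineligible). value′(g,s) = value(g,s) / T(s) ×
  mean_s T(s). The mean-T rescale keeps output on the input intensity
  scale; consequently "scale invariance" holds up to one global factor —
  all ratios between entries are preserved exactly, which is what the
  rank-based downstream statistics consume. Normalization is idempotent
  after the first application.
* **Imputation.** Missing values are replaced by the row's minimum observed
  value across *all* samples — a left-censoring floor per glycopeptide.
  All-missing rows cannot be imputed; they are dropped with a warning
  rather than zero-filled (zero would fabricate signal).
* **Charge-state collapse.** Rows sharing a site+composition id are summed
  (NaN+NaN stays NaN) before analysis; exposed as a switch.
* **QC.** CV% = 100·sd/mean (sample sd) across repeated control injections,
  at protein level (column sums over all rows) or per named peptide set.
* **Aggregation.** Feature classes: fucosylation degree 1–4, sialylation
  degree 1–4, antennarity 2/3/4, high-mannose. Degree and antennarity
  features are computed over complex-family glycans, so each degree axis
  partitions the complex set and totals are conserved exactly (degree-0
  complement included); high-mannose is its own class. Degrees above 4 pool
  into the 4 bucket by default. A row contributes to every class it belongs
  to (the axes deliberately overlap). Per-site scope emits site-qualified
  features.

## Statistics

* **Wilcoxon rank-sum**, two-sided. Exact null when min(n₁,n₂) ≤ 8 and the
  pooled sample is tie-free, otherwise normal approximation with tie and
  continuity corrections (via `scipy.stats.mannwhitneyu`). At n₁ = n₂ = 8
  the approximation tracks the exact p within 0.011 (worst case, measured
  exhaustively). Identical pooled values give p = 1.
* **BH-FDR** at 20% (step-up, via statsmodels), one family per contrast
  over all glyco-compounds plus aggregate features jointly; the family
  definition is recorded in the report header.
* **AUC** by the rank statistic U/(n₁n₂), identical to exhaustive pair
  counting with half-credit ties. Orientation is fixed (cases positive), so
  down-regulated markers yield AUC < 0.5; the report also carries the
  auto-oriented max(AUC, 1−AUC) with the orientation sign, matching ROC
  software that picks the direction automatically.
* **Operating points**: sensitivity at 90% specificity and specificity at
  90% sensitivity, maximized over empirical thresholds with no
  interpolation (conservative at small n; a useless marker scores ≈ 1 −
  level). Computed on the oriented score direction so they are meaningful
  for down-regulated markers.
* **Tier counts** are emitted both banded ((0.70–0.75], (0.75–0.80],
  (0.80–0.90], >0.90) and nested (>0.70 … >0.90), since published tallies
  are ambiguous between the two conventions.
* **Stratification** (phenotype / etiology / cirrhosis): a stratum is
  skipped, with a logged reason, when its total patient count in the
  contrast's analysis set is below `min_n` (default 10); retained strata
  re-run the unchanged marker evaluation, and a per-stratum vs whole-cohort
  AUC comparison table is emitted. Etiology strata may overlap (patients
  can carry several flags).

Contrasts default to control vs early, control vs late, early vs late, and
control vs pooled HCC. Missing AFP values are excluded pairwise when AFP is
benchmarked.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes; it
does **not** simulate spectra, retention times, or identification errors.

Defaults (the study conditions): groups 57/50/32
(control / early / late), glycoform counts 36/42/31/50 at N184/N207/N211/
N241, 5 decades of baseline dynamic range (log10-uniform; log-normal
alternative by config), biological SD 0.30 log10 units, technical CV 10%
(anchored to the observed technical reproducibility — guidance, not a
reproduction claim), per-sample handling factor CV 25% applied to all rows
*and* the heavy table (so normalization can remove it), left-censoring at
the 5th percentile of generated abundance, and Hp phenotype proportions per
group matching the published cohort table (deterministic counts = round(n·p),
remainder "unknown": e.g. 4/16/26 + 4 in the 50-sample early group).

Effect sizes are parameterized as **designed AUCs** and converted to
log-scale shifts by δ = Φ⁻¹(AUC)·σ√2 with σ = total within-group SD
(biological ⊕ technical). The default effect map raises fucosylated,
branched, high-mannose and highly sialylated classes in early HCC and
further in late HCC (designed AUCs 0.65–0.85), the monotone progression the
study describes; no per-glycoform effect sizes are published, so these
defaults are illustrative and labelled as such in the truth ledger. Within
each addressed class, half the rows carry the effect (`effect_fraction`),
leaving in-class nulls.

Left-censoring is a hard threshold on generated abundance, because
non-identified glycoforms are attributed to low abundance; missingness is
monotone in the threshold quantile. Censoring followed by minimum
imputation *attenuates* observed AUCs relative to the designed value — that
is a property of the imputation scheme, not a generator defect — so the
parameter-recovery check (designed AUC 0.90 at 200/group recovered within
±0.02 through the full normalize→impute→evaluate chain) runs with censoring
disabled, where the binormal identity is exact. What passing recovery shows
about real data is limited accordingly: it validates the arithmetic chain
and the normalization's removal of sample-level technical variation, not
robustness to informative missingness, batch effects, or non-log-normal
biology, none of which the generator emulates.

## Problem sizes in the test suite

Unit tests use an 8-sample, 20-glycoform cohort. Parameter recovery uses
200 samples/group with 159 glycoforms; the null false-discovery check uses
200 replicate cohorts of 12/12/2 samples with 40 glycoforms (the FDR bound
is a property of the procedure, not the cohort size); the end-to-end
determinism check runs the full 57/50/32 × 159 study shape twice and
compares reports byte for byte.

## Known limitations

* Antennarity/bisecting inference is heuristic (see above).
* The exact/asymptotic Wilcoxon switch creates a (documented, standard)
  discontinuity of up to ~0.011 in p at the n = 8 boundary.
* Top-3 heavy selection by global mean can change membership under extreme
  single-sample rescaling; with a properly spiked standard the selection is
  stable.
* The AFP benchmark in generated metadata is itself synthetic (designed
  AUC 0.79) and exists to exercise the comparison code path.
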