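# shatterkit

Simulation and detection of chromothripsis- and breakage–fusion–bridge
(BFB)-driven chromosomal amplification, with cohort copy-number analysis,
single-cell clonal-hierarchy inference and candidate-gene prioritization.

The package provides, end to end:

- **`sim_rearrange`** — a derivative-chromosome simulator (chromothripsis:
  shatter / lose / shuffle / invert / rejoin; BFB: iterated break–fold-back–
  duplicate; simple tandem duplications) that derives the implied
  copy-number profile and junction calls with ground-truth labels, plus
  cohort-, single-cell- and expression-level simulations (a recurrent
  chr21q22 amplification in ~25% of samples sharing a 2.7 Mb amplified core,
  elevated background CNA burden in carriers, a linear WT → JAK2 →
  JAK2+TP53 → +chr21amp clonal hierarchy with allele dropout, and
  dosage-driven expression with allelic skew).
- **`sv_io`** — BEDPE and VCF 4.2 breakend (BND) readers/writers, BED-like
  copy-number segment TSVs, and junction orientation classification
  (D / TD / HH / TT / TRA).
- **`sv_clustering`** — proximity clustering of junctions under a uniform
  breakend chance model, interleaving counts, an exact-multinomial /
  chi-square "fragment join" orientation-balance test, and CN oscillation
  run statistics.
- **`event_classify`** — simple vs complex (≥3 junctions) and
  chromothripsis-like classification (≥5 SVs, fragment-join p ≥ 0.05,
  ≥4 interleaved, oscillation runs ≥4 between 2 states / ≥5 between 3
  states; verdict at ≥3 of 4), fold-back inversion detection, and
  NHEJ-style (0–6 bp insertion) repair signatures.
- **`cn_cohort`** — gain / loss / CNN-LOH typing, chr21 amplification
  calling, the minimally amplified region (MAR) as the all-carrier interval
  intersection, a simplified permutation-based recurrence scan, pairwise
  lesion association (Fisher exact + phi), and the CNA-burden rank-sum
  comparison.
- **`clonal_hierarchy`** — clonal-state tabulation over per-cell genotypes
  and lesion-order inference by tolerance-corrected set containment.
- **`prioritize`** — single-cell rank-sum DE screen over the MAR panel,
  DE ∩ DA-promoter-peak candidate integration, and allele-specific
  expression skew tests against the copy-number dosage expectation.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
proportions, exhaustive classifier-threshold enumeration, simulator→caller
round trips, oracle equivalences, statistical calibration, structure
recovery, copy-mass conservation). The full suite takes ~3 minutes; the
Fisher-vs-hypergeometric full enumeration accounts for most of it.

## CLI

Everything is driven by one command with per-stage subcommands:

```sh
shatterkit run --out OUT --seed 42 [--config cfg.yaml]   # full pipeline
shatterkit sim --out DIR --seed 1 [--config cfg.yaml]
shatterkit cluster --junctions x.bedpe --segments segs.tsv --out DIR
shatterkit cohort --segments segs.tsv --lesions lesions.tsv --out DIR
shatterkit clones --cells cells.tsv --out DIR
shatterkit prioritize --counts counts.tsv --cells cells.tsv \
    --de de.tsv --da da.tsv --ase ase.tsv --out DIR
```

The config is a flat YAML of simulation parameters and stage thresholds
(`alpha`, `cn_threshold`, `tolerance`, `n_perm`, …); CLI flags override it.
`run` writes a `manifest.json` with the seed, full parameter set and
SHA-256 checksums of every output; reruns with the same config are
byte-identical.

### Conventions

Coordinates are 0-based half-open internally and in BEDPE/BED output;
VCF output is 1-based. BEDPE strand semantics: a deletion-type junction is
`(+,-)` with pos1 < pos2, a tandem duplication `(-,+)`, head-to-head
inverted `(+,+)`, tail-to-tail `(-,-)` — tools disagree on this, so round
trips through other software should be checked against this convention.
Unknown LOH status is encoded as `NA`, never as `0`.

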