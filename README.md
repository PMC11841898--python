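# msatcall

Microsatellite (STR) genotyping from capillary-electrophoresis
chromatograms, as a headless Python library and CLI.

Population geneticists still score microsatellite markers by running
fluorescently labelled PCR amplicons on a capillary sequencer and
reading allele lengths off the resulting chromatograms. `msatcall`
implements the computational core of that workflow with no GUI and no
instrument software: it parses ABIF/FSA files, delineates fluorescence
peaks and flags inter-channel crosstalk (pull-up), matches DNA-ladder
peaks to a size standard and calibrates a scan→bp polynomial with a
quality score, corrects inter-run size drift, and calls alleles while
accounting for the two PCR artifacts that multiply peaks per allele —
stutter (slippage products at whole-repeat offsets) and partial
adenylation (+A products 1 bp apart). A synthetic chromatogram
generator makes the entire pipeline testable without instrument data.

## The core methods

**Ladder matching.** Fragment mobility is smooth and monotone in
length, so the local slope Δscan/Δsize varies slowly along the ladder.
Detected peaks are matched to the standard's sizes by maximising
`B·k − Σ |Δ log(Δscan/Δsize)|` — a bonus per matched fragment minus the
total variation of the log-slope — exactly, by dynamic programming over
matching edges. Spurious peaks and missing fragments stay unassigned.

**Sizing.** Ordinary least squares, size = f(apex scan), polynomial
degree 1–3, solved by Cholesky decomposition of the normal equations on
centred/scaled scans. Sizing quality in [0, 1] is

```
score = max(0, 1 − max(ΔR²/ΔS)·10/3 − (n_s − n_p)/10)
```

with ΔR, ΔS the residual/scan differences of adjacent ladder peaks,
n_s sizes in the standard and n_p of them assigned.

**Offset correction.** Estimated sizes drift between runs; rather than
moving bins, sizes are corrected by `y = a + b·x`. Moving a bin-set
range [s, e] onto the peaks at [s′, e′] gives `b = (e′−s′)/(e−s)`,
`a = s′ − s·b`. For example, a = −6.40, b = 1.029 moves a 257-bp
fragment to 258.1 bp.

**Calling.** In-range, non-crosstalk peaks are clustered by seeded
absorption: each cluster seed absorbs shorter, markedly smaller peaks at
whole-repeat offsets (stutter) and near-equal peaks 1 bp away
(adenylation). The most intense member of each cluster — saturated
peaks ranked by clipped width — is the allele; allele count is capped
at the marker's ploidy (1 or 2), weaker clusters become "additional
fragments", and a batch cross-check re-splits adenylation merges that
other genotypes in the run contradict.

## Worked example

Generate a 4-sample synthetic plate, import, size, apply a panel, call
and export:

```sh
msatcall synth plate --n 4 --seed 42 --out plate
msatcall import plate/*.fsa --project proj.json
msatcall size --project proj.json --standard GeneScan-500 --degree 3
msatcall panel apply --project proj.json --panel-file panel.tsv
msatcall call --project proj.json
msatcall export --project proj.json --out genotypes.tsv
```

which prints

```
wrote 4 FSA file(s) and truth.tsv to plate
imported 4 sample(s)
sample001	quality=0.900
sample002	quality=1.000
sample003	quality=1.000
sample004	quality=1.000
initialized 16 genotype(s)
called 16 genotype(s)
wrote 16 genotype(s) to genotypes.tsv
```

The per-sample numbers are sizing-quality scores: all 16 GeneScan-500
fragments were assigned with near-zero residual jumps (sample001's 0.900
reflects a small residual wobble, still a usable ladder). The exported
table carries one row per sample × marker with bin-named alleles,
2-decimal sizes, additional fragments in their own column, and status:

```
sample     marker  allele1  allele2  size1   size2   status
sample001  Ma      258      266      258.00  266.00  called
sample001  Mb      132      140      132.00  140.00  called
sample001  Mc      184      208      183.97  208.00  called
sample001  Md      321               321.00          called
```

Every call matches the generator's ground truth (`plate/truth.tsv`);
haploid markers (Md) report a single allele, diploid homozygotes are
exported with the allele duplicated.

The same workflow is available as a library — `read_fsa`,
`detect_all_channels`, `size_ladder`, `cluster_peaks`/`call_genotype`,
`Project`/`export_genotypes` — see `docs/methods.md` for the models and
parameter meanings.

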