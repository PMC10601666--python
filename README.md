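# tracequant

Region-wise quantification of two-channel retrograde-tracing histology.
The pipeline takes coronal section images carrying a helper-virus channel
(mCherry/AAV) and a rabies channel (GFP/RV), detects fluorescent cells,
classifies starters by two-channel centroid overlap, registers sections to a
label-mask brain atlas via user landmarks, pools counts per injected
hemisphere inside an anterior–posterior analysis window, and compares sexes
per region with exact small-sample statistics.

## What it computes

Per hemisphere sample (the experimental unit):

- **PPS** (presynaptic per starter): presynaptic cells in a region divided by
  the sample's total starter count — a connectivity-strength normalization.
- **FPR** (fraction per region): presynaptic cells in a region divided by the
  sample's total presynaptic count — an input-composition measure.
- **Starter distribution**: starters per region over total starters.

Quality control keeps a hemisphere only if it has at least 20 detected
starter cells with strictly more than 60% of them inside the injection
target's region subtree. Per-region male-vs-female testing is restricted to
regions averaging strictly more than 30 presynaptic cells in either sex, uses
an exact two-sided Wilcoxon–Mann–Whitney test (full enumeration of group
assignments up to n = 12 per group, mid-ranks under ties), and controls the
false discovery rate at 5% with Benjamini–Hochberg. A binomial sign test (or
optional 2×2 Fisher variant) summarizes directional imbalance across regions.

No raw imagery ships with the package: the `fixtures` module generates
mirrored mosaic atlases, rendered two-channel sections with ground-truth cell
tables, and full dimorphic cohorts, so every stage is testable end to end.

## Layout

```
src/tracequant/
  atlas.py          region hierarchy, label-mask slices, AP window, aggregation
  fixtures.py       synthetic atlases, section rendering, cohort simulation
  detection.py      robust-threshold cell detection, circularity/SNR filters,
                    greedy two-channel starter matching
  registration.py   landmark affine fitting, region/hemisphere assignment
  quantify.py       hemisphere samples, QC gates, PPS/FPR/starter metrics
  stats.py          exact rank-sum, BH FDR, sign imbalance, cohort comparison
  io.py             CSV/JSON serialization of all artifacts
  cli.py            click CLI and pipeline orchestration
```

## CLI

```sh
tracequant simulate --seed 1 --out bundle/      # synthetic bundle + manifest
tracequant detect   --out bundle/               # per-section cell calls
tracequant register --out bundle/               # affines + region assignment
tracequant quantify --out bundle/               # cohort, QC log, metrics
tracequant stats    --out bundle/               # per-region comparison table
tracequant run-all  --config cfg.yaml --seed 1 --out bundle/
```

All stages read one YAML/JSON config (defaults mirror the QC thresholds
above); command-line `--seed` overrides the config. `simulate` writes a
manifest with content hashes, and reruns are byte-identical for a fixed seed.

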