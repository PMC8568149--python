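# methtrace

Nanopore sequencing calls 5-methylcytosine directly from raw signal, and
callers such as **nanopolish**, **f5c** and **Megalodon** emit per-read,
per-CpG methylation evidence as log-likelihood ratios. These outputs are
large (a single flow cell yields tens of millions of calls), come in
caller-specific formats, and are not directly usable by the
differential-methylation tooling most analysts rely on.

`methtrace` is a Python toolkit that closes that gap for people analysing
nanopore methylation data on ordinary hardware:

* **Import** — parse nanopolish/f5c and Megalodon per-read call tables
  into a minimal common record: `(sample, chromosome, 1-based position,
  log-likelihood ratio, read id)`. Grouped multi-CpG nanopolish calls are
  split into single-site records using the CG offsets of their sequence
  context. Parsing streams, so memory use is independent of file size.
* **Store** — persist records position-sorted, bgzip-compressed and
  tabix-indexed. Region queries decompress only the overlapping blocks,
  so a gene-sized window is retrieved in milliseconds from a
  genome-scale file.
* **Export** — binarize calls by the sign of the LLR (optionally with an
  ambiguity dead-zone) into site × sample methylated/unmethylated count
  matrices, written in the input formats of bsseq-, DSS- and edgeR-style
  DMR analyses, plus the log-methylation-ratio matrix
  `log2((Me + c)/(Un + c))` (prior count `c = 2`) used for sample
  embeddings.
* **Profiles & plots** — the per-call statistic maps to a probability via
  the sigmoid `p = 1/(1+e^{-LLR})`. On top of that: per-site means,
  feature-relative scaling with fixed-width flanks, binned means,
  lowess smoothing, equal-feature-weight aggregate (metagene-style)
  profiles, per-read *spaghetti* plots and read heatmaps with exon
  tracks, CpG ticks and DMR shading, region-class box plots, and
  classical MDS / PCA sample embeddings of the most variable sites.
* **Synthesize** — generate caller-format fixtures from a declarative
  methylation landscape with known per-site ground truth, so every step
  above is testable without downloads.

## Worked example

Simulate two groups of three samples whose methylation levels differ by
Δμ = 0.4 (μ = 0.7 vs 0.3) at 150 CpG sites with ~50× coverage, build a
store, count calls per site, and embed the samples:

```python
import tempfile
from pathlib import Path

from methtrace import build_store, count_sites, log_methy_ratio
from methtrace.dimred import mds_embedding, select_top_variable_sites
from methtrace.synth import simulate_records, two_group_landscape

landscape = two_group_landscape(n_sites=150, mu_high=0.7, delta=0.4, coverage=50)
records, samples = [], []
for i in range(3):
    for group in "AB":
        sample = f"{group}{i + 1}"
        samples.append((sample, group))
        records.extend(simulate_records(landscape, sample, group, seed=10 * i + ord(group)))

workdir = Path(tempfile.mkdtemp())
store = build_store(records, workdir / "demo.tsv.bgz", samples=samples)
counts = count_sites(store)
print("count matrix:", counts.methylated.shape, "sites x samples,",
      counts.n_discarded, "ambiguous calls discarded")

lmr = log_methy_ratio(counts, prior_count=2)
embedding = mds_embedding(select_top_variable_sites(lmr, k=500))
print(embedding.coordinates.round(2))
```

which prints

```
count matrix: (150, 6) sites x samples, 0 ambiguous calls discarded
           dim1  dim2
sample_id
A1         1.03 -0.31
B1        -0.99 -0.20
A2         0.93 -0.11
B2        -0.99  0.01
A3         1.07  0.41
B3        -1.04  0.19
```

The first MDS dimension cleanly separates the two methylation groups
(all A samples positive, all B negative), exactly as expected when the
dominant source of between-sample variation is the simulated group
difference; the second dimension spreads the replicate pairs.

The same flow is available from the shell:

```sh
methtrace synth --config landscape.toml --seed 3 -o calls/
methtrace convert --caller nanopolish --sample s1 --group ctrl \
    --sample s2 --group case -o store.tsv.bgz calls/s1_nanopolish.tsv calls/s2_nanopolish.tsv
methtrace query chr1:5000-5300 store.tsv.bgz
methtrace export --flavor dss -o dss/ store.tsv.bgz
methtrace plot region --region chr1:4500-8500 --out spaghetti.png store.tsv.bgz
```

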