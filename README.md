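# motupipe

Reverse-taxonomy analysis of COI barcode surveys: cluster sequences into
molecular operational taxonomic units (MOTUs) first, attach morphological
identities afterwards.  Built for the situation deep-sea benthic surveys
face — two widely separated sampling regions, singleton-heavy samples,
and mostly undescribed species — where classical taxonomy alone cannot
deliver diversity and connectivity estimates in time.

The pipeline covers, per taxon group:

* **Screening** — stop-codon (pseudogene) screen in the three forward
  frames under the invertebrate mitochondrial code.
* **Clustering** — greedy incremental identity clustering
  (longest-first, first-hit, default 97% identity with 400 bp minimum
  coverage) into MOTUs, with singleton/shared/exclusive accounting by
  license area.
* **Distances & trees** — pairwise identity, uncorrected p-distance and
  Kimura 2-parameter distance
  `d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`;
  neighbor-joining trees (midpoint-rooted) from p-distance matrices.
* **Beta diversity** — unweighted UniFrac between stations on the NJ
  tree; cosine similarity between MOTU abundance vectors; nMDS (Kruskal
  stress-1), one-way ANOSIM (Clarke's R, 999 permutations) and Mantel
  tests (Pearson r, 5000 permutations) against geographic distance.
* **Richness** — Chao1, Chao2 and first-order jackknife extrapolation per
  license area with percent-registration (100·S_obs/estimate).
* **Concordance** — agreement between genotypic clusters and
  morpho-species labels (concordant / split / lumped, adjusted Rand
  index) across a descending identity-threshold sweep (0.97 → 0.90 →
  0.80).
* **Synthetic data** — a K80 sequence simulator plus a two-region survey
  generator with known ground truth (star-shaped MOTUs, log-series
  abundances, distance-decay placement), used throughout the test suite.

## Worked example

Generate a synthetic two-region survey (10 + 5 stations ~1300 km apart,
polychaetes and isopods, known true partition) and run the full analysis:

```bash
$ motupipe simulate --seed 1 -o survey
wrote 260 sequences, 15 stations, 173 observed MOTUs to survey

$ motupipe run-all survey/sequences.fasta survey/metadata.tsv survey/stations.tsv \
    --seed 1 -o results
[polychaete] 180 sequences -> 121 MOTUs (80 singletons); ANOSIM R(UniFrac)=0.52 p=0.001; Mantel r(cosine,geo)=-0.37 p=0.0012
[isopod] 80 sequences -> 52 MOTUs (34 singletons); ANOSIM R(UniFrac)=0.32 p=0.007; Mantel r(cosine,geo)=-0.34 p=0.0008
results bundle -> results
```

Reading this output: 180 polychaete sequences collapse into 121 MOTUs of
which 80 are singletons (the singleton-heavy regime typical of abyssal
macrofauna); the ANOSIM R of 0.52 (p = 0.001) says the two license areas
host significantly different assemblages, and the negative Mantel r of
−0.37 says compositional similarity between stations falls as geographic
distance grows — the generator's built-in distance decay, recovered by
the statistics.

Richness extrapolation from the clustered polychaetes:

```bash
$ motupipe diversity results/polychaete/abundance.tsv
chao1: S_obs=121 estimate=244.1 +/- 38.3 registration=49.6%
chao2: S_obs=121 estimate=241.1 +/- 36.6 registration=50.2%
jackknife1: S_obs=121 estimate=197.5 registration=61.3%
```

i.e. the 121 observed MOTUs are an estimated ~50% of the regional pool —
the survey-completeness figure a contractor would report.  The bundle
also contains per-group newick trees, UniFrac/cosine matrices, nMDS
coordinates and plots, per-area richness tables and a concordance report;
every stage is also available as its own subcommand (`simulate`,
`screen`, `cluster`, `distances`, `tree`, `unifrac`, `community`,
`diversity`, `concordance`).

The same workflow in Python:

```python
import motupipe as mp

ds = mp.simulate_dataset(mp.SimConfig(), seed=1)
bundle = mp.run_pipeline(ds.records, ds.stations, mp.RunConfig(seed=1))
poly = bundle.groups["polychaete"]
print(poly.summary["n_motus"], poly.mantel_cosine_geo.statistic)
```

## Layout

```
src/motupipe/
  seq_io.py       FASTA/newick/TSV I/O, pseudogene screen
  distances.py    alignment, identity, p/K2P distances, matrices
  cluster.py      greedy MOTU clustering, abundance, area accounting
  phylogeny.py    neighbor joining, midpoint rooting
  unifrac.py      unweighted UniFrac
  community.py    cosine, geographic distance, nMDS, ANOSIM, Mantel
  diversity.py    Chao1/Chao2/jackknife, registration
  concordance.py  MOTU vs morpho-species agreement, threshold sweep
  simulate.py     K80 simulator, two-region survey generator
  pipeline.py     end-to-end orchestration
  cli.py          `motupipe` command-line interface
docs/methods.md   models, defaults, calibration, limitations
```
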