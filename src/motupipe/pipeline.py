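"""End-to-end orchestration: screen -> cluster -> distances -> tree ->
UniFrac -> community statistics -> richness -> concordance.

Each taxon group (polychaetes, isopods) is analyzed separately; the
license-area grouping enters only at the ANOSIM/nMDS/richness stage.  All
stochastic steps are seeded through :class:`RunConfig`, so a run is
byte-reproducible: identical config + inputs give identical outputs,
including permutation p-values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster import ClusterConfig, MotuTable, build_abundance_matrix, greedy_cluster, summarize_motus
from .community import (
    TestResult,
    anosim,
    cosine_similarity_matrix,
    geographic_distance_matrix,
    mantel,
    nmds,
    plot_nmds,
)
from .concordance import compare_partitions
from .distances import DistanceMatrix, build_distance_matrix, group_mean_distances
from .diversity import RichnessEstimate, chao1, chao2, jackknife1, registration
from .phylogeny import neighbor_joining
from .seq_io import (
    SampleMap,
    SequenceRecord,
    StationRecord,
    screen_pseudogenes,
    write_newick,
)
from .unifrac import unifrac_matrix

__all__ = ["RunConfig", "GroupResults", "ResultsBundle", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Settings of one pipeline run (defaults mirror the survey conventions)."""

    taxon_groups: tuple[str, ...] = ("polychaete", "isopod")
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    n_permutations_anosim: int = 999
    n_permutations_mantel: int = 5000
    geo_mode: str = "euclidean_degrees"
    seed: int = 0
    nmds_restarts: int = 50
    screen: bool = True
    tree_metric: str = "p"

    def digest(self) -> str:
        payload = json.dumps(
            {**asdict(self), "version": __version__}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroupResults:
    taxon_group: str
    motus: MotuTable
    summary: dict
    abundance: pd.DataFrame
    group_distances: pd.DataFrame | None
    tree: object
    unifrac: DistanceMatrix
    cosine: DistanceMatrix
    nmds_unifrac: object
    nmds_cosine: object
    anosim_unifrac: TestResult
    anosim_cosine: TestResult
    mantel_cosine_geo: TestResult
    mantel_unifrac_geo: TestResult
    mantel_cosine_unifrac: TestResult
    richness: list[RichnessEstimate]
    concordance: object


@dataclass
class ResultsBundle:
    config: RunConfig
    groups: dict[str, GroupResults]
    richness_pooled: dict[str, list[RichnessEstimate]]
    n_screened_out: int
    manifest: dict


def _richness_for_area(abundance: pd.DataFrame) -> list[RichnessEstimate]:
    per_motu = abundance.sum(axis=0)
    observed = per_motu[per_motu > 0]
    incidence = abundance.T.loc[observed.index]
    return [chao1(observed.to_numpy()), chao2(incidence), jackknife1(incidence)]


def richness_table(
    abundance: pd.DataFrame, area_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per-license-area richness extrapolation (rows shaped like a survey table)."""
    rows = []
    for area in sorted(set(area_of.values())):
        sub = abundance.loc[[s for s in abundance.index if area_of[s] == area]]
        for est in _richness_for_area(sub):
            rows.append(
                {
                    "area": area,
                    "estimator": est.estimator,
                    "S_obs": est.s_obs,
                    "N": int(sub.to_numpy().sum()),
                    "estimate": round(est.estimate, 1),
                    "sd": round(est.sd, 1) if est.sd is not None else "",
                    "registration_pct": registration(est.s_obs, est.estimate),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    records: Sequence[SequenceRecord],
    stations: Sequence[StationRecord],
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> ResultsBundle:
    """Run the full reverse-taxonomy analysis on one dataset."""
    sample_map = SampleMap.build(records, stations)
    area_of = sample_map.area_of
    geo = geographic_distance_matrix(stations, mode=config.geo_mode)

    n_screened_out = 0
    if config.screen:
        records, failed = screen_pseudogenes(records)
        n_screened_out = len(failed)
        if failed:
            logger.warning("%d records failed the stop-codon screen", n_screened_out)

    groups: dict[str, GroupResults] = {}
    pooled_abundance: list[pd.DataFrame] = []
    for gi, group in enumerate(config.taxon_groups):
        recs = [r for r in records if r.taxon_group == group]
        if len(recs) < 3:
            logger.warning("taxon group %r has <3 sequences; skipped", group)
            continue
        logger.info("[%s] %d sequences", group, len(recs))
        motus = greedy_cluster(recs, config.cluster)
        summary = summarize_motus(motus, sample_map.station_of, area_of)
        logger.info(
            "[%s] %d MOTUs (%d singletons)",
            group, summary["n_motus"], summary["n_singletons"],
        )
        abundance = build_abundance_matrix(motus, sample_map.station_of)
        pooled_abundance.append(abundance)

        # distances and NJ tree (p-distance by convention)
        dm = build_distance_matrix(recs, metric=config.tree_metric)
        tree = neighbor_joining(dm)

        # morpho-label group mean distances where labels exist
        labels = {r.id: r.morpho_label for r in recs if r.morpho_label}
        group_dist = None
        multi_labels = {
            k: v for k, v in labels.items()
            if sum(1 for x in labels.values() if x == v) >= 2
        }
        if multi_labels:
            k2p = build_distance_matrix(
                [r for r in recs if r.id in multi_labels], metric="k2p"
            )
            group_dist = group_mean_distances(k2p, multi_labels)

        # UniFrac over stations
        inc = {r.id: {r.station_id} for r in recs}
        uf = unifrac_matrix(tree, inc, [s.station_id for s in stations])
        cosine = cosine_similarity_matrix(abundance)

        present = [s for s in geo.labels if s in uf.labels and s in cosine.labels]
        geo_g = geo.reorder(present)
        uf_g = uf.reorder(present)
        cos_g = cosine.reorder(present)
        grp_of = {s: area_of[s] for s in present}

        seed = config.seed + gi  # distinct but derived stream per group
        res = GroupResults(
            taxon_group=group,
            motus=motus,
            summary=summary,
            abundance=abundance,
            group_distances=group_dist,
            tree=tree,
            unifrac=uf,
            cosine=cosine,
            nmds_unifrac=nmds(uf_g, seed=seed, n_restarts=config.nmds_restarts),
            nmds_cosine=nmds(cos_g, seed=seed, n_restarts=config.nmds_restarts),
            anosim_unifrac=anosim(
                uf_g, grp_of, config.n_permutations_anosim, seed=seed
            ),
            anosim_cosine=anosim(
                cos_g, grp_of, config.n_permutations_anosim, seed=seed
            ),
            mantel_cosine_geo=mantel(
                cos_g, geo_g, config.n_permutations_mantel, seed=seed
            ),
            mantel_unifrac_geo=mantel(
                uf_g, geo_g, config.n_permutations_mantel, seed=seed
            ),
            mantel_cosine_unifrac=mantel(
                cos_g, uf_g, config.n_permutations_mantel, seed=seed
            ),
            richness=_richness_for_area(abundance).copy(),
            concordance=compare_partitions(
                motus, {r.id: r.morpho_label for r in recs}
            ),
        )
        groups[group] = res

    # per-area richness pooled over taxon groups (survey-table convention)
    richness_pooled: dict[str, list[RichnessEstimate]] = {}
    if pooled_abundance:
        pooled = (
            pd.concat(pooled_abundance, axis=1)
            .fillna(0)
            .astype(int)
        )
        pooled.columns = [f"c{i}" for i in range(pooled.shape[1])]
        for area in sorted(set(area_of.values())):
            rows = [s for s in pooled.index if area_of[s] == area]
            if rows:
                richness_pooled[area] = _richness_for_area(pooled.loc[rows])

    manifest = {
        "version": __version__,
        "config_digest": RunConfig.digest(config),
        "seed": config.seed,
        "n_input_records": len(records) + n_screened_out,
        "n_screened_out": n_screened_out,
        "taxon_groups": {g: r.summary for g, r in groups.items()},
    }
    bundle = ResultsBundle(
        config=config,
        groups=groups,
        richness_pooled=richness_pooled,
        n_screened_out=n_screened_out,
        manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(bundle, stations, Path(outdir))
    return bundle


def _write_bundle(
    bundle: ResultsBundle, stations: Sequence[StationRecord], outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    area_of = {s.station_id: s.license_area for s in stations}
    for g, res in bundle.groups.items():
        d = outdir / g
        d.mkdir(exist_ok=True)
        res.motus.to_tsv(d / "clusters.tsv")
        res.abundance.to_csv(d / "abundance.tsv", sep="\t")
        if res.group_distances is not None:
            res.group_distances.to_csv(d / "group_mean_k2p_pct.tsv", sep="\t")
        write_newick(res.tree, d / "nj_tree.nwk")
        res.unifrac.to_tsv(d / "unifrac.tsv")
        res.cosine.to_tsv(d / "cosine.tsv")
        res.nmds_unifrac.coordinates.to_csv(d / "nmds_unifrac.tsv", sep="\t")
        res.nmds_cosine.coordinates.to_csv(d / "nmds_cosine.tsv", sep="\t")
        plot_nmds(res.nmds_unifrac, area_of, str(d / "nmds_unifrac.svg"))
        plot_nmds(res.nmds_cosine, area_of, str(d / "nmds_cosine.svg"))
        stats = {
            "summary": res.summary,
            "anosim": {
                "unifrac": asdict(res.anosim_unifrac),
                "cosine": asdict(res.anosim_cosine),
            },
            "mantel": {
                "cosine_vs_geo": asdict(res.mantel_cosine_geo),
                "unifrac_vs_geo": asdict(res.mantel_unifrac_geo),
                "cosine_vs_unifrac": asdict(res.mantel_cosine_unifrac),
            },
            "nmds_stress": {
                "unifrac": res.nmds_unifrac.stress,
                "cosine": res.nmds_cosine.stress,
            },
            "concordance": res.concordance.summary_text(),
        }
        (d / "stats.json").write_text(json.dumps(stats, indent=2, default=str))
        richness_table(res.abundance, area_of).to_csv(
            d / "richness.tsv", sep="\t", index=False
        )
    pooled_rows = []
    for area, ests in bundle.richness_pooled.items():
        for est in ests:
            pooled_rows.append(
                {
                    "area": area,
                    "estimator": est.estimator,
                    "S_obs": est.s_obs,
                    "estimate": round(est.estimate, 1),
                    "sd": round(est.sd, 1) if est.sd is not None else "",
                    "registration_pct": registration(est.s_obs, est.estimate),
                }
            )
    pd.DataFrame(pooled_rows).to_csv(outdir / "richness_pooled.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, default=str)
    )
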