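"""Cohort-level model and results objects.

`CohortNetworkModel` bundles the three inputs — background interactome,
expression z-score matrix, two-group phenotype labels — with a
:class:`~ppicohort.config.RunConfig`. ``fit()`` executes the full
analysis: per-sample seed selection, network construction, Jaccard
distances, UPGMA clustering, Fisher cluster enrichment, and for every
significant cluster the per-group consensus networks, specificity
labels, hub ranking, Louvain modularity, and the separation score s_AB
between the two groups' unique protein sets. The returned
`CohortNetworkResults` carries all estimates, exposes ``summary()``,
and writes the full artifact set with ``save()``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __about__
from .cluster import (
    ClusterTest,
    Dendrogram,
    DistanceMatrix,
    cophenetic_correlation,
    pairwise_distances,
    significant_clusters,
    upgma,
    write_cluster_report,
)
from .config import RunConfig, auto_min_count
from .consensus import (
    ConsensusNetwork,
    HubReport,
    ModularityResult,
    build_consensus,
    hub_proteins,
    label_specificity,
    louvain_modularity,
    write_consensus_edge_tsv,
    write_graphml,
    write_hub_report,
)
from .expression import (
    ExpressionMatrix,
    PhenotypeLabels,
    read_phenotype,
    read_zscore_matrix,
    select_seeds,
)
from .interactome import Interactome, read_edge_tsv, read_string_links
from .networks import SampleGraph, build_sample_network
from .separation import SeparationResult, separation_sab

logger = logging.getLogger(__name__)


@dataclass
class ClusterAnalysis:
    """Everything computed for one significant cluster."""

    cluster: ClusterTest
    consensus: dict[int, ConsensusNetwork] = field(default_factory=dict)
    specificity: dict[str, str] = field(default_factory=dict)
    hubs: dict[int, HubReport] = field(default_factory=dict)
    modularity: dict[int, ModularityResult] = field(default_factory=dict)
    separation: SeparationResult | None = None


@dataclass
class CohortNetworkResults:
    """Fitted cohort analysis: per-sample graphs, distance matrix,
    dendrogram, cluster tests, and per-cluster group analyses."""

    model: "CohortNetworkModel"
    sample_graphs: list[SampleGraph]
    distances: DistanceMatrix
    dendrogram: Dendrogram
    cophenetic: float
    clusters: list[ClusterAnalysis]

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def summary(self) -> str:
        """Human-readable run summary."""
        cfg = self.config
        lines = [
            "Cohort PPI network analysis",
            "=" * 60,
            f"samples analysed:        {len(self.sample_graphs)}",
            f"seed genes per sample:   {cfg.seed_count} ({cfg.direction}regulated)",
            f"max path length:         {cfg.max_path_length} "
            f"(connector mode: {cfg.connector_mode})",
            f"cophenetic correlation:  {self.cophenetic:.4f}",
            f"significant clusters:    {len(self.clusters)} "
            f"(alpha={cfg.alpha}, height<={cfg.meta_cluster_threshold})",
        ]
        for i, ca in enumerate(self.clusters, start=1):
            t = ca.cluster
            lines.append("-" * 60)
            lines.append(
                f"cluster {i} [{t.node_id}]: n={t.n} "
                f"(group1={t.a}, group2={t.b}), p={t.p:.3g}"
            )
            for grp in (1, 2):
                if grp not in ca.consensus:
                    continue
                cons = ca.consensus[grp]
                hubs = ca.hubs.get(grp)
                mod = ca.modularity.get(grp)
                hub_str = (
                    ", ".join(f"{s}({d})" for s, d in hubs.entries) if hubs else "-"
                )
                q_str = f"Q={mod.q:.4f}, {mod.n_modules} modules" if mod else "-"
                lines.append(
                    f"  group {grp} consensus: {cons.n_nodes} nodes / "
                    f"{cons.n_edges} edges; {q_str}"
                )
                lines.append(f"    hubs: {hub_str}")
            if ca.separation is not None:
                s = ca.separation
                verdict = "separated" if s.s_ab > 0 else "overlapping"
                lines.append(
                    f"  separation of unique protein sets: s_AB={s.s_ab:.4f} "
                    f"({verdict}; <d_AA>={s.mean_daa:.3f}, "
                    f"<d_BB>={s.mean_dbb:.3f}, <d_AB>={s.mean_dab:.3f})"
                )
        return "\n".join(lines)

    def save(self, outdir: str | Path | None = None) -> Path:
        """Write the full artifact set; returns the output directory.

        Artifacts: Newick dendrogram, distance-matrix TSV, cluster
        report TSV, per-cluster per-group GraphML + edge TSV + hub TSV,
        separation TSV, JSON manifest (config echo, version, input
        checksums, artifact list), and a plain-text summary.
        """
        cfg = self.config
        outdir = Path(outdir if outdir is not None else cfg.output_directory)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts: list[str] = []

        def record(name: str) -> Path:
            artifacts.append(name)
            return outdir / name

        self.dendrogram.write_newick(record("dendrogram.nwk"))
        self.distances.write_tsv(record("distance_matrix.tsv"))
        all_tests = [ca.cluster for ca in self.clusters]
        write_cluster_report(all_tests, record("cluster_report.tsv"), cfg.alpha)
        for i, ca in enumerate(self.clusters, start=1):
            for grp in (1, 2):
                if grp not in ca.consensus:
                    continue
                cons = ca.consensus[grp]
                mod = ca.modularity.get(grp)
                write_graphml(
                    cons,
                    record(f"cluster{i}_group{grp}.graphml"),
                    specificity=ca.specificity,
                    modules=mod.partition if mod else None,
                    max_vertices=cfg.max_vertices_to_render,
                )
                write_consensus_edge_tsv(
                    cons, record(f"cluster{i}_group{grp}_edges.tsv")
                )
                if grp in ca.hubs:
                    write_hub_report(
                        ca.hubs[grp], record(f"cluster{i}_group{grp}_hubs.tsv")
                    )
            if ca.separation is not None:
                ca.separation.write_tsv(record(f"cluster{i}_separation.tsv"))
        with open(record("summary.txt"), "w") as fh:
            fh.write(self.summary() + "\n")

        manifest = {
            "tool": "ppicohort",
            "version": __about__.__version__,
            "config": cfg.echo(),
            "input_checksums": self.model.input_checksums(),
            "artifacts": sorted(artifacts) + ["manifest.json"],
            "n_samples": len(self.sample_graphs),
            "cophenetic_correlation": self.cophenetic,
            "n_significant_clusters": len(self.clusters),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return outdir


class CohortNetworkModel:
    """Cohort PPI network model over an interactome, an expression
    z-score matrix, and two-group phenotype labels.

    Parameters
    ----------
    interactome
        Background PPI graph; all sample-network edges come from here.
    expression
        Gene x sample z-score matrix.
    labels
        Sample -> group assignment (groups 1 and 2, both non-empty).
    config
        Run parameters; defaults to ``RunConfig()`` defaults.
    """

    def __init__(
        self,
        interactome: Interactome,
        expression: ExpressionMatrix,
        labels: PhenotypeLabels,
        config: RunConfig | None = None,
    ) -> None:
        self.interactome = interactome
        self.expression = expression
        self.labels = labels
        self.config = config if config is not None else RunConfig()
        self._input_paths: dict[str, str] = {}
        labels.require_two_groups()
        self.samples = [s for s in expression.samples if s in labels.assignment]
        if len(self.samples) < 2:
            raise ValueError("need at least 2 labeled samples present in the matrix")
        missing = [s for s in labels.assignment if s not in set(expression.samples)]
        if missing:
            logger.warning(
                "%d labeled sample(s) absent from the expression matrix", len(missing)
            )

    @classmethod
    def from_files(cls, config: RunConfig) -> "CohortNetworkModel":
        """Build the model from the file paths in ``config``.

        The interactome path is read as STRING links if its records
        carry integer 0-1000 scores, otherwise as a 2-3 column edge TSV.
        """
        itx = _read_interactome(
            config.interactome,
            config.min_interactome_score,
            config.default_edge_confidence,
        )
        expr = read_zscore_matrix(config.expression)
        labels = read_phenotype(config.phenotype)
        model = cls(itx, expr, labels, config)
        model._input_paths = {
            "interactome": config.interactome,
            "expression": config.expression,
            "phenotype": config.phenotype,
        }
        return model

    def input_checksums(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name, path in self._input_paths.items():
            if path and Path(path).exists():
                digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
                out[name] = f"sha256:{digest}"
        return out

    def fit(self) -> CohortNetworkResults:
        """Run the full analysis and return the results object."""
        cfg = self.config
        logger.info("selecting %d %s-regulated seeds per sample", cfg.seed_count, cfg.direction)
        graphs = [
            build_sample_network(
                select_seeds(self.expression, s, cfg.seed_count, cfg.direction),
                self.interactome,
                max_path_length=cfg.max_path_length,
                connector_mode=cfg.connector_mode,
            )
            for s in self.samples
        ]
        logger.info("computing pairwise Jaccard distances (%s)", cfg.jaccard_mode)
        dist = pairwise_distances(graphs, mode=cfg.jaccard_mode)
        dendro = upgma(dist)
        coph = cophenetic_correlation(dist, dendro)
        logger.info("cophenetic correlation: %.4f", coph)
        tests = significant_clusters(
            dendro,
            self.labels,
            alpha=cfg.alpha,
            min_size=cfg.min_cluster_size,
            max_height=cfg.meta_cluster_threshold,
        )
        logger.info("%d significant cluster(s) at alpha=%g", len(tests), cfg.alpha)
        graph_by_sample = {g.sample: g for g in graphs}
        analyses = [
            self._analyse_cluster(test, graph_by_sample) for test in tests
        ]
        return CohortNetworkResults(
            model=self,
            sample_graphs=graphs,
            distances=dist,
            dendrogram=dendro,
            cophenetic=coph,
            clusters=analyses,
        )

    def _analyse_cluster(
        self, test: ClusterTest, graph_by_sample: dict[str, SampleGraph]
    ) -> ClusterAnalysis:
        cfg = self.config
        analysis = ClusterAnalysis(cluster=test)
        for grp in (1, 2):
            members = sorted(test.members & self.labels.members(grp))
            member_graphs = [graph_by_sample[s] for s in members if s in graph_by_sample]
            if not member_graphs:
                logger.warning(
                    "cluster %s: no group-%d members, skipping consensus",
                    test.node_id,
                    grp,
                )
                continue
            min_count = cfg.consensus_min_count or auto_min_count(len(member_graphs))
            cons = build_consensus(
                member_graphs,
                mode=cfg.consensus_mode,
                min_count=min_count,
                interactome=self.interactome,
                group=str(grp),
                max_path_length=cfg.max_path_length,
                connector_mode=cfg.connector_mode,
            )
            analysis.consensus[grp] = cons
            if cons.n_nodes:
                analysis.hubs[grp] = hub_proteins(cons, k=cfg.hub_k)
                analysis.modularity[grp] = louvain_modularity(
                    cons,
                    resolution=cfg.modularity_resolution,
                    rng_seed=cfg.rng_seed,
                    weighted=cfg.modularity_weighted,
                )
        if 1 in analysis.consensus and 2 in analysis.consensus:
            analysis.specificity = label_specificity(
                analysis.consensus[1], analysis.consensus[2]
            )
            unique_a = {n for n, lab in analysis.specificity.items() if lab == "unique_to_A"}
            unique_b = {n for n, lab in analysis.specificity.items() if lab == "unique_to_B"}
            try:
                analysis.separation = separation_sab(self.interactome, unique_a, unique_b)
            except ValueError as err:
                logger.warning(
                    "cluster %s: separation score unavailable (%s)", test.node_id, err
                )
        return analysis


def _read_interactome(
    path: str, min_score: int, default_confidence: float
) -> Interactome:
    """Dispatch on dialect: STRING links if the first data record's third
    field is an integer score, else generic edge TSV."""
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.strip()
                break
    fields = first.split() if "\t" not in first else first.split("\t")
    if len(fields) == 3:
        token = fields[2]
        if fields[0].lower().startswith("protein1"):
            return read_string_links(path, min_score=min_score)
        try:
            int(token)
            return read_string_links(path, min_score=min_score)
        except ValueError:
            pass
    return read_edge_tsv(path, default_confidence=default_confidence)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Load inputs per ``config``, fit the model, write all artifacts.

    Returns the output directory. A ``run.log`` capturing warnings is
    written alongside the artifacts; any stage failure propagates after
    being logged with the stage name.
    """
    outdir = Path(outdir if outdir is not None else config.output_directory)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setLevel(logging.INFO)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ppicohort")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "load inputs"
    try:
        model = CohortNetworkModel.from_files(config)
        stage = "fit"
        results = model.fit()
        stage = "save artifacts"
        results.save(outdir)
    except Exception:
        logging.getLogger(__name__).error("pipeline failed during stage: %s", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
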