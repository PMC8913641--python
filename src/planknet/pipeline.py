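"""End-to-end orchestration: data in, one network per turbidity class out.

The run ingests (or synthesises) biomass data, splits samples by
turbidity class, autoscales each class table, infers the
significance-thresholded signed correlation network, computes global
attributes, node/edge centralities and communities per class, computes
per-sample diversity and between-class tests, and writes everything as
delimited text plus a JSON manifest.  Deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__
from .community import autoscale, compare_classes, diversity_table
from .inference import pearson_matrix, threshold_network
from .io import (
    BiomassMatrix,
    TurbidityClassSpec,
    assign_classes,
    read_biomass_table,
    write_network,
)
from .metrics import (
    CentralityTable,
    GlobalNetworkAttributes,
    communities,
    global_attributes,
    node_centralities,
)
from .synthetic import make_study_fixture

__all__ = ["RunConfig", "ClassResult", "RunReport", "run"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a wide biomass table) or
    ``synthetic`` (True = generate the three-class study fixture) must
    be given.
    """

    input_path: str | None = None
    synthetic: bool = False
    class_spec: TurbidityClassSpec = field(default_factory=TurbidityClassSpec)
    alpha: float = 0.05
    correction: str = "none"
    log_base: str | int = "e"
    include_isolated: bool = True
    community_k: dict[str, int] | None = None
    output_dir: str | None = None
    seed: int = 0
    delimiter: str = ","
    decimal: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if bool(self.input_path) == bool(self.synthetic):
            raise ValueError("exactly one of input_path / synthetic must be provided")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class ClassResult:
    """Everything computed for one turbidity class."""

    turbidity_class: str
    n_samples: int
    n_taxa: int
    dropped_taxa: list[str]
    network: nx.Graph
    attributes: GlobalNetworkAttributes
    centralities: CentralityTable
    communities: list[frozenset]


@dataclass
class RunReport:
    """Return value of :func:`run`: per-class results plus summaries."""

    classes: dict[str, ClassResult]
    diversity: pd.DataFrame
    comparisons: list
    warnings: list[str]
    manifest: dict
    files: list[str]


def _load_inputs(config: RunConfig) -> dict[str, BiomassMatrix]:
    if config.synthetic:
        return make_study_fixture(config.seed)
    m = read_biomass_table(config.input_path, delimiter=config.delimiter, decimal=config.decimal)
    m = assign_classes(m, config.class_spec)
    return m.split_by_class()


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis; see the module docstring for the stages."""
    logging.basicConfig(level=config.log_level)
    warnings: list[str] = []
    by_class = _load_inputs(config)

    class_results: dict[str, ClassResult] = {}
    diversity_frames = []
    for cls in sorted(by_class, key=["HT", "MT", "LT"].index):
        m = by_class[cls]
        try:
            scaled, dropped = autoscale(m)
            if dropped:
                warnings.append(f"{cls}: dropped zero-variance taxa {dropped}")
            corr = pearson_matrix(scaled, alpha=config.alpha)
            net = threshold_network(corr, correction=config.correction)
            attrs = global_attributes(net, include_isolated=config.include_isolated)
            cents = node_centralities(net)
            k = (config.community_k or {}).get(cls)
            try:
                comms = communities(net, k=k)
            except ValueError as exc:  # edgeless network
                warnings.append(f"{cls}: communities skipped ({exc})")
                comms = [frozenset([n]) for n in net.nodes]
        except Exception as exc:
            raise RuntimeError(f"[class {cls}] {type(exc).__name__}: {exc}") from exc
        class_results[cls] = ClassResult(
            turbidity_class=cls,
            n_samples=m.shape[0],
            n_taxa=m.shape[1],
            dropped_taxa=dropped,
            network=net,
            attributes=attrs,
            centralities=cents,
            communities=comms,
        )
        div = diversity_table(m, log_base=config.log_base)
        div.insert(0, "turbidity_class", cls)
        diversity_frames.append(div)

    diversity = pd.concat(diversity_frames, ignore_index=True)

    comparisons = []
    if len(class_results) >= 2:
        for var in ("shannon_h", "pielou_j", "richness"):
            groups = {
                cls: diversity.loc[diversity["turbidity_class"] == cls, var].dropna().to_numpy()
                for cls in class_results
            }
            groups = {g: v for g, v in groups.items() if v.size >= 2}
            if len(groups) >= 2:
                comparisons.append(compare_classes(groups, "anova", config.alpha, variable=var))
                comparisons.append(compare_classes(groups, "kruskal_wallis", config.alpha, variable=var))

    manifest = {
        "config": _config_dict(config),
        "versions": {
            "planknet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "classes": {
            cls: {
                "n_samples": res.n_samples,
                "n_taxa": res.n_taxa,
                "n_edges": res.network.number_of_edges(),
                "dropped_taxa": res.dropped_taxa,
                "n_communities": len(res.communities),
            }
            for cls, res in class_results.items()
        },
        "warnings": warnings,
    }

    files: list[str] = []
    if config.output_dir:
        files = _write_outputs(Path(config.output_dir), class_results, diversity, comparisons, manifest)
        manifest["files"] = files

    return RunReport(class_results, diversity, comparisons, warnings, manifest, files)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["class_spec"] = dataclasses.asdict(config.class_spec)
    return d


def _write_outputs(outdir, class_results, diversity, comparisons, manifest) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    attr_rows = []
    for cls, res in class_results.items():
        row = {"turbidity_class": cls, **res.attributes.to_dict()}
        attr_rows.append(row)
    p = outdir / "global_attributes.tsv"
    pd.DataFrame(attr_rows).to_csv(p, sep="\t", index=False)
    files.append(p.name)

    for cls, res in class_results.items():
        for fmt, name in (("edgelist", f"network_{cls}.edges.tsv"), ("graphml", f"network_{cls}.graphml")):
            fp = outdir / name
            write_network(res.network, fp, format=fmt)
            files.append(fp.name)
        fp = outdir / f"node_centrality_{cls}.tsv"
        res.centralities.nodes.to_csv(fp, sep="\t", index=False)
        files.append(fp.name)
        fp = outdir / f"edge_centrality_{cls}.tsv"
        res.centralities.edges.to_csv(fp, sep="\t", index=False)
        files.append(fp.name)
        fp = outdir / f"communities_{cls}.tsv"
        rows = [
            {"community": i, "taxon": t}
            for i, comm in enumerate(res.communities)
            for t in sorted(comm, key=str)
        ]
        pd.DataFrame(rows, columns=["community", "taxon"]).to_csv(fp, sep="\t", index=False)
        files.append(fp.name)

    fp = outdir / "diversity.tsv"
    diversity.to_csv(fp, sep="\t", index=False)
    files.append(fp.name)

    rows = []
    for c in comparisons:
        rows.append(
            {
                "variable": c.variable,
                "test": c.test,
                "statistic": c.statistic,
                "df": "/".join(map(str, c.df)),
                "p_value": c.p_value,
                "tukey_groups": json.dumps(c.tukey_groups) if c.tukey_groups else "",
            }
        )
    fp = outdir / "comparisons.tsv"
    pd.DataFrame(rows, columns=["variable", "test", "statistic", "df", "p_value", "tukey_groups"]).to_csv(
        fp, sep="\t", index=False
    )
    files.append(fp.name)

    fp = outdir / "manifest.json"
    fp.write_text(json.dumps(manifest, indent=2, default=str, sort_keys=True))
    files.append(fp.name)
    return files
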