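"""End-to-end orchestration: load (or simulate) → cascade → inheritance →
network → enrichment, with a JSON run manifest for provenance.

The config is one YAML document with sections::

    inputs:            # either this ...
      fixture: table1          # packaged worked example, or
      vcfs: [fam1.vcf, ...]    # per-family VCFs
      sidecars: [fam1.annotations.tsv, ...]
      ped: cohort.ped
    simulate:          # ... or this (mutually exclusive with inputs)
      n_families: 9
      seed: 17
      ...any SimConfig field...
    cascade:           # CascadeConfig fields
      maf_threshold: 0.01
    inheritance:       # InheritanceConfig fields
      max_parent_miscalls: 0
    network:
      edges: string_edges.tsv   # omit to use the packaged synthetic list
      threshold: 0.150
      top: 6
    enrichment:
      gmt: sets.gmt             # omit to use the packaged synthetic GMT
      alpha: 0.05

Outputs: funnel.tsv, inheritance.tsv, hubs.tsv, enrichment.tsv,
manifest.json in the chosen output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .cascade import CascadeConfig, FunnelReport, run_cascade
from .enrichment import enrichment_to_frame, run_enrichment
from .errors import ConfigError
from .fixtures import load_demo_genesets, load_ppi_edges, load_table1_fixture
from .inheritance import InheritanceCall, InheritanceConfig, calls_to_frame, classify_cohort
from .io import read_edges, read_family_vcf, read_gmt, read_ped
from .network import average_degree, build_graph, graph_summary, mcc_scores, top_hubs
from .simulate import SimConfig, simulate_cohort, write_cohort
from .types import AnnotatedVariant, FamilyGenotypes


@dataclass
class RunResult:
    out_dir: Path
    funnel: FunnelReport
    calls: list[InheritanceCall]
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(
    config: dict, out_dir: Path
) -> tuple[list[AnnotatedVariant], dict[str, FamilyGenotypes], dict[str, str]]:
    digests: dict[str, str] = {}
    if ("inputs" in config) == ("simulate" in config):
        raise ConfigError("config must contain exactly one of 'inputs' or 'simulate'")

    if "simulate" in config:
        sim_cfg = SimConfig(**config["simulate"])
        cohort = simulate_cohort(sim_cfg)
        sim_dir = out_dir / "simulated"
        paths = write_cohort(cohort, sim_dir)
        digests.update({name: _sha256(p) for name, p in sorted(paths.items())})
        return cohort.variants, cohort.families, digests

    inputs = config["inputs"]
    if inputs.get("fixture") == "table1":
        variants, families = load_table1_fixture()
        return variants, {f.family_id: f for f in families}, digests
    for field in ("vcfs", "sidecars", "ped"):
        if field not in inputs:
            raise ConfigError(f"inputs section missing {field!r}")
    if len(inputs["vcfs"]) != len(inputs["sidecars"]):
        raise ConfigError("vcfs and sidecars must pair up one-to-one")
    ped_path = Path(inputs["ped"])
    if not ped_path.exists():
        raise ConfigError(f"PED file {ped_path} does not exist")
    for p in map(Path, list(inputs["vcfs"]) + list(inputs["sidecars"])):
        if not p.exists():
            raise ConfigError(f"input file {p} does not exist")
    pedigree = read_ped(ped_path)
    digests[ped_path.name] = _sha256(ped_path)
    variants = []
    families = {}
    for vcf, sidecar in zip(inputs["vcfs"], inputs["sidecars"]):
        vs, fam = read_family_vcf(vcf, sidecar, pedigree)
        variants.extend(vs)
        families[fam.family_id] = fam
        digests[Path(vcf).name] = _sha256(Path(vcf))
        digests[Path(sidecar).name] = _sha256(Path(sidecar))
    return variants, families, digests


def run_all(config: Union[str, Path, dict], out_dir: Union[str, Path]) -> RunResult:
    """Run the full pipeline from a config file or dict."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    variants, families, digests = _load_inputs(config, out)

    cascade_cfg = CascadeConfig(**config.get("cascade", {}))
    funnel = run_cascade(variants, cascade_cfg)
    funnel.to_frame().to_csv(out / "funnel.tsv", sep="\t", index=False)

    survivors = {d.key for d in funnel.final_survivors}
    surviving = [v for v in variants if v.key in survivors]
    inh_cfg = InheritanceConfig(**config.get("inheritance", {}))
    calls, mode_counts = classify_cohort(surviving, families, inh_cfg)
    calls_to_frame(calls).to_csv(out / "inheritance.tsv", sep="\t", index=False)

    net_cfg = config.get("network", {})
    genes = sorted({v.gene for v in surviving})
    if "edges" in net_cfg:
        edges = read_edges(net_cfg["edges"])
        digests[Path(net_cfg["edges"]).name] = _sha256(Path(net_cfg["edges"]))
    else:
        edges = load_ppi_edges()
    threshold = float(net_cfg.get("threshold", 0.150))
    graph = build_graph(genes, edges, threshold)
    summary = graph_summary(graph)
    summary.to_csv(out / "hubs.tsv", sep="\t", index=False)
    hubs = top_hubs(mcc_scores(graph), int(net_cfg.get("top", 6)))

    enr_cfg = config.get("enrichment", {})
    if "gmt" in enr_cfg:
        collection = read_gmt(enr_cfg["gmt"])
        digests[Path(enr_cfg["gmt"]).name] = _sha256(Path(enr_cfg["gmt"]))
    else:
        collection = load_demo_genesets()
    query = set(genes) & set(collection.universe)
    rows = run_enrichment(query, collection, alpha=float(enr_cfg.get("alpha", 0.05)))
    enrichment_to_frame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    manifest = {
        "tool": "trioprio",
        "version": __version__,
        "started": started,
        "config": config,
        "input_digests": digests,
        "seed": config.get("simulate", {}).get("seed"),
        "stage_counts": {
            "input_variants": funnel.input_count,
            **{f"after_{s}": n for s, n in funnel.survivors.items()},
            "inheritance_calls": len(calls),
            "modes": {m.value: c for m, c in mode_counts.items()},
            "network_nodes": graph.n_nodes,
            "network_edges": graph.n_edges,
            "network_mean_degree": round(average_degree(graph), 3) if graph.n_nodes else None,
            "top_hubs": hubs,
            "enrichment_rows": len(rows),
            "enrichment_significant": sum(r.significant for r in rows),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return RunResult(out_dir=out, funnel=funnel, calls=calls, manifest=manifest)
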