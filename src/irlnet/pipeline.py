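"""End-to-end orchestration: from synthetic fixtures (or user tables) to the
final hub-lncRNA call.

Stage order: simulate/load -> probe re-annotation check -> SAM differential
expression on both contrasts -> Venn intersection -> global triple network
-> hypergeometric network extraction -> bicluster module analysis ->
weighted co-expression modules -> intersection of the network-module
lncRNAs with the top co-expression hubs.  Every stage's inputs, outputs,
seed and losses (dropped samples, deleted probes, test counts) are recorded
in a JSON run manifest so a run can be audited and reproduced byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import diffexpr, module_clustering, reannotation, synthetic_data, triple_network
from . import wgcna_lite
from .containers import LNCRNA, MRNA
from .synthetic_data import SyntheticConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    deg_p: float = 0.01
    edge_p: float = 0.01
    trait_p: float = 0.01
    compare_p: float = 0.05
    wgcna: wgcna_lite.WgcnaParams = field(default_factory=wgcna_lite.WgcnaParams)
    n_perm: int = 1000
    top_k_hubs: int = 7
    seed: int = 42
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        for name in ("deg_p", "edge_p", "trait_p", "compare_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class HubReport:
    irlmn_module_lncrnas: list[str]
    wgcna_hub_lncrnas: list[str]
    intersection: list[str]
    evidence: pd.DataFrame     # per intersected hub: degree, k_within, module, RBPs

    def __post_init__(self) -> None:
        inter = set(self.intersection)
        if not (inter <= set(self.irlmn_module_lncrnas)
                and inter <= set(self.wgcna_hub_lncrnas)):
            raise ValueError("intersection must be contained in both hub lists")


def intersect_hubs(
    module: module_clustering.HeatmapModule | None,
    wgcna_hubs: pd.DataFrame,
    irlmn: triple_network.Irlmn | None = None,
    net: triple_network.TripleNetwork | None = None,
) -> HubReport:
    """Intersect network-module lncRNAs with the ranked co-expression hubs.

    Evidence columns (network degree, intramodular connectivity, module,
    binding RBPs) are joined from both sides for each intersected hub.
    """
    module_lnc = list(module.lncrnas) if module is not None else []
    hub_lnc = list(wgcna_hubs["feature"]) if len(wgcna_hubs) else []
    inter = sorted(set(module_lnc) & set(hub_lnc))
    rows = []
    for lnc in inter:
        hub_row = wgcna_hubs[wgcna_hubs["feature"] == lnc].iloc[0]
        rbps: set[str] = set()
        if irlmn is not None:
            for e in irlmn.edges:
                if e.lncrna == lnc:
                    rbps |= e.shared_rbps
        elif net is not None:
            rbps = set(net.lnc_to_rbp.get(lnc, frozenset()))
        rows.append({
            "feature": lnc,
            "irlmn_degree": irlmn.degree.get(lnc, 0) if irlmn is not None else 0,
            "k_within": float(hub_row["k_within"]),
            "wgcna_module": hub_row["module"],
            "binding_rbps": ",".join(sorted(rbps)),
        })
    evidence = pd.DataFrame(
        rows, columns=["feature", "irlmn_degree", "k_within", "wgcna_module",
                       "binding_rbps"],
    )
    return HubReport(
        irlmn_module_lncrnas=sorted(module_lnc),
        wgcna_hub_lncrnas=hub_lnc,
        intersection=inter,
        evidence=evidence,
    )


@dataclass
class PipelineResult:
    degs_case_control: dict[str, list[str]]
    degs_paired: dict[str, list[str]]
    intersected: dict[str, list[str]]
    network: triple_network.TripleNetwork
    irlmn: triple_network.Irlmn
    module: module_clustering.HeatmapModule | None
    wgcna_assignment: wgcna_lite.ModuleAssignment | None
    wgcna_hubs: pd.DataFrame
    report: HubReport
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage on the synthetic fixture defined by the config.

    Any stage failure aborts with the stage name attached; the manifest up
    to that point is preserved on the raised exception.
    """
    manifest: dict = {"seed": cfg.seed, "stages": [], "config": {
        "deg_p": cfg.deg_p, "edge_p": cfg.edge_p, "trait_p": cfg.trait_p,
        "compare_p": cfg.compare_p, "n_perm": cfg.n_perm,
        "top_k_hubs": cfg.top_k_hubs,
        "synthetic": asdict(cfg.synthetic), "wgcna": asdict(cfg.wgcna),
    }}
    stage = "simulate"
    try:
        # --- synthetic inputs ------------------------------------------
        lnc_tab, mrna_tab, truth = synthetic_data.generate_interaction_tables(
            cfg.synthetic
        )
        bundle = synthetic_data.generate_expression_dataset(cfg.synthetic, truth)
        hits, expected_map = synthetic_data.generate_probe_alignments(
            cfg.synthetic, truth
        )
        manifest["stages"].append({
            "stage": stage,
            "n_lnc_pairs": len(lnc_tab), "n_mrna_pairs": len(mrna_tab),
            "n_features": bundle.case_control.matrix.shape[0],
        })

        # --- probe re-annotation (consistency check on the fixture) ----
        stage = "reannotation"
        pmap = reannotation.filter_alignments(hits)
        agrees = pmap.mapping == expected_map.mapping
        manifest["stages"].append({
            "stage": stage, "n_probe_sets": len(pmap.mapping),
            "n_transcripts": len(pmap.transcripts),
            "matches_expected": bool(agrees),
        })

        # --- differential expression -----------------------------------
        stage = "diffexpr"
        res_cc = diffexpr.sam_analysis(
            bundle.case_control, threshold=cfg.deg_p, n_perm=cfg.n_perm,
            seed=cfg.seed % 2**31,
        )
        res_p = diffexpr.sam_analysis(
            bundle.paired, threshold=cfg.deg_p, n_perm=cfg.n_perm,
            seed=(cfg.seed + 1) % 2**31,
        )
        degs_cc = diffexpr.call_degs(res_cc, cfg.deg_p)
        degs_p = diffexpr.call_degs(res_p, cfg.deg_p)
        inter = diffexpr.intersect_contrasts(degs_cc, degs_p)
        manifest["stages"].append({
            "stage": stage,
            "case_control": {bt: len(v) for bt, v in degs_cc.items()},
            "paired": {bt: len(v) for bt, v in degs_p.items()},
            "intersection": {bt: len(v) for bt, v in inter.items()},
            "s0": [res_cc.s0, res_p.s0],
            "n_permutations": [res_cc.n_permutations, res_p.n_permutations],
        })

        # --- triple network + IRLMN ------------------------------------
        stage = "triple_network"
        net = triple_network.build_global_network(lnc_tab, mrna_tab)
        mapped_lnc, mapped_mrna = triple_network.map_degs(
            net, inter[LNCRNA], inter[MRNA]
        )
        irlmn = triple_network.extract_irlmn(
            net, mapped_lnc, mapped_mrna, threshold=cfg.edge_p
        )
        manifest["stages"].append({
            "stage": stage, "m_rbps": net.m,
            "mapped_lncrnas": len(mapped_lnc), "mapped_mrnas": len(mapped_mrna),
            "n_tests": sum(
                1 for l in mapped_lnc for mr in mapped_mrna
                if net.lnc_to_rbp.get(l, frozenset())
                & net.mrna_to_rbp.get(mr, frozenset())
            ),
            "irlmn_lnc_nodes": len(irlmn.lnc_nodes),
            "irlmn_mrna_nodes": len(irlmn.mrna_nodes),
            "irlmn_edges": len(irlmn.edges),
        })

        # --- bicluster module analysis ----------------------------------
        stage = "module_clustering"
        module = None
        if irlmn.edges:
            mat = module_clustering.association_matrix(irlmn)
            if mat.shape[0] >= 2 and mat.shape[1] >= 2:
                row_z, col_z, _ = module_clustering.bicluster(mat)
                kr, kc = module_clustering.choose_cuts(row_z, col_z, mat)
                module = module_clustering.extract_module(
                    row_z, col_z, mat, kr, kc, irlmn=irlmn
                )
            else:
                module = module_clustering.HeatmapModule(
                    lncrnas=sorted(irlmn.lnc_nodes),
                    mrnas=sorted(irlmn.mrna_nodes),
                    rbps=sorted(set().union(*(e.shared_rbps for e in irlmn.edges))),
                    mean_score=float(pd.Series(
                        [1 - e.p for e in irlmn.edges]).mean()),
                )
        manifest["stages"].append({
            "stage": stage,
            "module_lncrnas": len(module.lncrnas) if module else 0,
            "module_mrnas": len(module.mrnas) if module else 0,
            "module_rbps": len(module.rbps) if module else 0,
        })

        # --- co-expression modules on the intersected DE features -------
        # (replication across both contrasts prunes permutation false
        # positives before network construction)
        stage = "wgcna"
        de_features = inter[LNCRNA] + inter[MRNA]
        assignment = None
        hubs = pd.DataFrame(columns=["feature", "module", "k_within"])
        dropped: list[str] = []
        if len(de_features) >= max(10, cfg.wgcna.min_module_size):
            ds = bundle.case_control.subset_features(de_features)
            assignment, adj, dropped = wgcna_lite.run_wgcna(
                ds.matrix,
                trait=(bundle.case_control.labels == bundle.case_control.contrast[0])
                .astype(float),
                params=cfg.wgcna,
            )
            if assignment.modules:
                if assignment.trait_stats is not None:
                    target = assignment.trait_stats["r2"].idxmax()
                else:
                    target = assignment.modules[0]
                hubs = wgcna_lite.hub_weights(
                    adj, assignment.labels, target, top_k=cfg.top_k_hubs,
                    biotype=ds.biotype, restrict_biotype=LNCRNA,
                )
        manifest["stages"].append({
            "stage": stage, "n_de_features": len(de_features),
            "dropped_samples": dropped,
            "modules": assignment.modules if assignment else [],
            "trait_stats": (
                assignment.trait_stats.reset_index().to_dict("records")
                if assignment is not None and assignment.trait_stats is not None
                else []
            ),
            "n_hubs": len(hubs),
        })

        # --- final hub intersection -------------------------------------
        stage = "hub_report"
        report = intersect_hubs(module, hubs, irlmn=irlmn, net=net)
        manifest["stages"].append({
            "stage": stage,
            "irlmn_module_lncrnas": report.irlmn_module_lncrnas,
            "wgcna_hub_lncrnas": report.wgcna_hub_lncrnas,
            "intersection": report.intersection,
            "planted_hub": truth.hub_lncrna,
        })
    except Exception as exc:
        exc.manifest = manifest          # type: ignore[attr-defined]
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        degs_case_control=degs_cc, degs_paired=degs_p, intersected=inter,
        network=net, irlmn=irlmn, module=module,
        wgcna_assignment=assignment, wgcna_hubs=hubs, report=report,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: PipelineConfig, result: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        files[name] = p

    save("irlmn_edges", result.irlmn.edge_table())
    if result.module is not None:
        save("module_members", pd.DataFrame({
            "feature": result.module.lncrnas + result.module.mrnas,
            "role": [LNCRNA] * len(result.module.lncrnas)
            + [MRNA] * len(result.module.mrnas),
        }))
        save("module_rbp_table", module_clustering.module_rbp_table(
            result.module, result.network))
    if result.wgcna_assignment is not None:
        save("wgcna_assignment", result.wgcna_assignment.labels.rename("module")
             .rename_axis("feature").reset_index())
        if result.wgcna_assignment.trait_stats is not None:
            save("wgcna_trait", result.wgcna_assignment.trait_stats.reset_index())
    save("wgcna_hubs", result.wgcna_hubs)
    save("hub_report", result.report.evidence)
    if result.irlmn.edges:
        files["irlmn_graphml"] = triple_network.export_network(
            result.irlmn, out / "irlmn.graphml", format="graphml"
        )
    result.manifest["outputs"] = {
        name: {"path": str(p), "sha256": _sha256(p)} for name, p in files.items()
    }
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str)
    )
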