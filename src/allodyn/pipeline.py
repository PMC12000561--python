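"""Config-driven orchestration of the full analysis flow.

simulate complex -> sample trajectory -> superpose -> correlations /
mode analysis -> energy decomposition -> dynamic network -> optimal
path; simulate + fit assays; consolidated structured-text report.

The configuration is a flat YAML mapping; unknown keys are rejected by
name.  Every numeric tunable is echoed to the log at stage start, and
all randomness flows from the single ``seed`` key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
import networkx as nx

from allodyn import dynamics, energy, fitting, io, network, synth
from allodyn.errors import ConfigError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

#: every config key with its default; unknown keys are rejected.
DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "allodyn_out",
    "stages": ["simulate", "trajectory", "correlations", "nma", "eda",
               "network", "paths", "assays"],
    # complex generation
    "n_protein_residues": 10,
    "n_nucleotides": 4,
    "include_cofactor": True,
    "close_pairs": [],                 # [[label_a, label_b], ...]
    "abasic_nucleotides": [],
    # trajectory generation
    "n_frames": 500,
    "background_correlation": 0.2,
    "planted_path": [],                # node labels
    "planted_correlation": 0.9,
    "node_variance": synth.DEFAULT_NODE_VARIANCE,
    "contact_schedule": [],            # [[label_a, label_b, fraction], ...]
    "rigid_jitter": 0.0,
    "superpose": "auto",               # auto | always | never
    # network / analysis tunables
    "cutoff_A": network.DEFAULT_CUTOFF,
    "persistence": network.DEFAULT_PERSISTENCE,
    "correlation_floor": network.CORRELATION_FLOOR,
    "base_nitrogen_rule": {},
    "scale_ee": energy.SCEE,
    "scale_nb": energy.SCNB,
    "eda_cutoff": None,
    "eda_fragment": "kind cofactor",
    "path_source": None,               # default: cofactor node
    "path_target": None,               # default: first abasic/base node
    # assay simulation + fitting
    "assay_noise": 0.05,
    "sto_params": {"a0": 20.0, "k2": 1.2},
    "sto_design": {"time_min": [0.25, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 10],
                   "replicates": 3, "enzyme_nM": 100.0, "substrate_nM": 20.0},
    "mto_params": {"a0": 4.0, "k2": 1.2, "k3": 0.05},
    "mto_design": {"time_min": [0.25, 0.5, 0.75, 1, 1.5, 2, 3, 5, 8, 12, 20, 30],
                   "replicates": 3, "enzyme_nM": 5.0, "substrate_nM": 20.0},
    "binding_params": {"bmax": 100.0, "kd": 2.0},
    "binding_design": {"conc": [0.05, 0.1, 0.25, 0.5, 1, 2, 4, 8, 16, 32, 64]},
    "rif_params": {"f": 5e-8},
    "rif_design": {"n_plates": 24, "viable_mean": 1e8, "viable_cv": 0.2},
}


@dataclass
class PipelineConfig:
    """Validated flat configuration; see :data:`DEFAULTS` for keys."""

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [k for k in self.values if k not in DEFAULTS]
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        merged = {**DEFAULTS, **self.values}
        bad = [s for s in merged["stages"] if s not in DEFAULTS["stages"]]
        if bad:
            raise ConfigError(f"unknown stage(s): {bad}")
        self.values = merged

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls(values=doc)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output."""

    config: PipelineConfig
    topology: io.Topology | None = None
    reference: np.ndarray | None = None
    trajectory: io.Trajectory | None = None
    nodes: network.NodeSet | None = None
    correlations: dynamics.CorrelationMatrix | None = None
    modes: dynamics.ModeSpectrum | None = None
    energy_table: energy.EnergyTable | None = None
    net: network.DynamicNetwork | None = None
    betweenness: pd.DataFrame | None = None
    path: network.PathResult | None = None
    fits: dict[str, Any] = field(default_factory=dict)
    report_text: str = ""


def _cofactor_label(nodes: network.NodeSet) -> str | None:
    for n in nodes.nodes:
        if n.kind == "cofactor":
            return n.label
    return None


def _ap_label(nodes: network.NodeSet) -> str | None:
    for n in nodes.nodes:
        if "abasic" in n.flags:
            return n.label
    for n in nodes.nodes:
        if n.kind == "base":
            return n.label
    return None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write the report bundle."""
    cfg = config
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    res = PipelineResult(config=cfg)
    report: list[str] = ["# allodyn pipeline report", ""]
    seed = int(cfg["seed"])

    if "simulate" in stages:
        logger.info("stage simulate: %d protein residues, %d nucleotides, "
                    "cofactor=%s", cfg["n_protein_residues"],
                    cfg["n_nucleotides"], cfg["include_cofactor"])
        topo, ref = synth.make_toy_complex(
            int(cfg["n_protein_residues"]), int(cfg["n_nucleotides"]),
            include_cofactor=bool(cfg["include_cofactor"]), seed=seed,
            close_pairs=tuple(tuple(p) for p in cfg["close_pairs"]),
            abasic_nucleotides=tuple(cfg["abasic_nucleotides"]),
        )
        res.topology, res.reference = topo, ref
        io.write_topology(topo, outdir / "topology.yaml")
        io.write_trajectory(io.Trajectory(ref[None]), topo,
                            outdir / "reference.pdb")
        report += [f"[simulate] atoms={topo.n_atoms} "
                   f"close_pairs={len(cfg['close_pairs'])}"]

    if res.topology is None:
        raise ConfigError("pipeline requires the simulate stage (or preloaded "
                          "topology) before analysis stages")
    nodes = network.assign_nodes(res.topology, res.reference,
                                 cfg["base_nitrogen_rule"] or None)
    res.nodes = nodes

    if "trajectory" in stages:
        labels = nodes.labels()
        planted_idx = tuple(labels.index(l) for l in cfg["planted_path"])
        spec = synth.CovarianceSpec(
            n_nodes=len(nodes),
            background=float(cfg["background_correlation"]),
            planted_path=planted_idx,
            planted_correlation=float(cfg["planted_correlation"]),
            node_variance=cfg["node_variance"],
            seed=seed,
        )
        cov = synth.build_covariance(spec)
        schedule = {(a, b): float(f) for a, b, f in cfg["contact_schedule"]}
        logger.info("stage trajectory: %d frames, background C=%.3f, "
                    "planted C=%.3f on %d nodes, %d scheduled contacts",
                    cfg["n_frames"], spec.background,
                    spec.planted_correlation, len(planted_idx), len(schedule))
        traj = synth.sample_trajectory(
            res.topology, res.reference, cov, int(cfg["n_frames"]),
            contact_schedule=schedule, seed=seed,
            rigid_jitter=float(cfg["rigid_jitter"]),
            cutoff=float(cfg["cutoff_A"]),
        )
        mode = cfg["superpose"]
        if mode not in ("auto", "always", "never"):
            raise ConfigError(f"superpose must be auto/always/never, got {mode!r}")
        # superposition removes net rigid-body motion; for a lab-frame
        # synthetic field it would also damp collective correlations, so
        # "auto" aligns only when rigid jitter was actually applied
        if mode == "always" or (mode == "auto" and float(cfg["rigid_jitter"]) > 0):
            ca = io.select_fragment(res.topology, "kind protein name CA")
            res.trajectory = dynamics.superpose(traj, res.reference, ca)
        else:
            res.trajectory = traj
        truth = {
            "seed": seed,
            "background_correlation": spec.background,
            "planted_path": list(cfg["planted_path"]),
            "planted_correlation": spec.planted_correlation,
            "contact_schedule": [[a, b, f] for (a, b), f in schedule.items()],
        }
        (outdir / "ground_truth.yaml").write_text(yaml.safe_dump(truth))
        report += [f"[trajectory] frames={traj.n_frames} nodes={len(nodes)}"]

    if "correlations" in stages and res.trajectory is not None:
        res.correlations = dynamics.correlation_matrix(res.trajectory, nodes)
        res.correlations.to_frame().to_csv(
            outdir / "correlations.csv", float_format=_FLOAT_FMT
        )
        report += ["[correlations] written correlations.csv"]

    if "nma" in stages and res.trajectory is not None:
        res.modes = dynamics.pca_modes(res.trajectory, nodes)
        res.modes.to_frame().to_csv(outdir / "modes.csv", index=False,
                                    float_format=_FLOAT_FMT)
        top = ", ".join(f"{f * 100:.1f}%" for f in res.modes.fractions[:3])
        report += [f"[nma] leading mode fractions: {top}"]

    if "eda" in stages and res.trajectory is not None:
        frag = io.select_fragment(res.topology, cfg["eda_fragment"])
        logger.info("stage eda: fragment %r, 1-4 scaling ee=%.4f nb=%.4f",
                    cfg["eda_fragment"], cfg["scale_ee"], cfg["scale_nb"])
        res.energy_table = energy.fragment_interaction_energy(
            res.trajectory, res.topology, frag,
            scale_ee=float(cfg["scale_ee"]), scale_nb=float(cfg["scale_nb"]),
            cutoff=cfg["eda_cutoff"],
        )
        res.energy_table.frames.to_csv(outdir / "eda_frames.csv", index=False,
                                       float_format=_FLOAT_FMT)
        res.energy_table.per_partner.to_csv(
            outdir / "eda_partners.csv", index=False, float_format=_FLOAT_FMT
        )
        se = res.energy_table.standard_errors()
        report += [
            "[eda] fragment %s: total %.4f +/- %.4f kcal/mol "
            "(coulomb %.4f, vdw %.4f)" % (
                cfg["eda_fragment"], res.energy_table.mean_total, se["total"],
                res.energy_table.mean_coulomb, res.energy_table.mean_vdw,
            )
        ]

    if "network" in stages and res.trajectory is not None:
        logger.info("stage network: cutoff=%.2f A, persistence>%.2f, "
                    "floor=%.0e", cfg["cutoff_A"], cfg["persistence"],
                    cfg["correlation_floor"])
        contacts = network.contact_map(
            res.trajectory, res.topology, nodes,
            cutoff=float(cfg["cutoff_A"]),
            persistence=float(cfg["persistence"]),
        )
        res.net = network.build_network(
            contacts, res.correlations, nodes,
            persistence=float(cfg["persistence"]),
            correlation_floor=float(cfg["correlation_floor"]),
            cutoff=float(cfg["cutoff_A"]),
        )
        res.betweenness = network.edge_betweenness(res.net)
        edges = res.net.edge_table().merge(
            res.betweenness, on=["node_i", "node_j"], how="left"
        )
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
        gml = nx.relabel_nodes(
            res.net.graph, {n.node_id: n.label for n in nodes.nodes}, copy=True
        )
        nx.write_graphml(gml, outdir / "network.graphml")
        report += [f"[network] {res.net.graph.number_of_edges()} edges "
                   f"among {len(nodes)} nodes"]

    if "paths" in stages and res.net is not None:
        source = cfg["path_source"] or _cofactor_label(nodes)
        target = cfg["path_target"] or _ap_label(nodes)
        if source and target:
            res.path = network.optimal_path(res.net, source, target)
            if res.path.found:
                pd.DataFrame({"node": res.path.nodes}).to_csv(
                    outdir / "optimal_path.csv", index=False
                )
                report += [
                    "[paths] %s -> %s: %s (total weight %.4f)" % (
                        source, target, " - ".join(res.path.nodes),
                        res.path.total_weight,
                    )
                ]
            else:
                report += [f"[paths] no path between {source} and {target}"]
        else:
            report += ["[paths] skipped: no source/target node available"]

    if "assays" in stages:
        res.fits = _run_assays(cfg, seed, report)

    report_text = "\n".join(report) + "\n"
    (outdir / "report.txt").write_text(report_text)
    res.report_text = report_text
    return res


def _run_assays(cfg: PipelineConfig, seed: int, report: list[str]) -> dict:
    fits: dict[str, Any] = {}
    noise = float(cfg["assay_noise"])
    sto = synth.simulate_glycosylase(synth.AssaySpec(
        "STO", cfg["sto_params"], cfg["sto_design"], noise, seed + 1))
    fits["sto"] = fitting.fit_sto(sto)
    mto = synth.simulate_glycosylase(synth.AssaySpec(
        "MTO", cfg["mto_params"], cfg["mto_design"], noise, seed + 2))
    fits["mto"] = fitting.fit_mto(mto)
    x, y = synth.simulate_binding(synth.AssaySpec(
        "binding", cfg["binding_params"], cfg["binding_design"], noise,
        seed + 3))
    fits["binding"] = fitting.fit_binding(x, y)
    resistant, viable = synth.simulate_rif(synth.AssaySpec(
        "rif", cfg["rif_params"], cfg["rif_design"], 0.0, seed + 4))
    fits["mutfreq"] = fitting.mutation_frequency(resistant, viable)
    report += [
        "[assays] STO k2=%.4f /min (true %.4f)" % (
            fits["sto"].k2, cfg["sto_params"]["k2"]),
        "[assays] MTO a0=%.4f nM k2=%.4f k3=%.4f active_fraction=%.3f" % (
            fits["mto"].a0, fits["mto"].k2, fits["mto"].k3,
            fits["mto"].active_fraction),
        "[assays] binding KD=%.4g Bmax=%.4g%%%s" % (
            fits["binding"].kd, fits["binding"].bmax,
            " (upper limit)" if fits["binding"].upper_limit else ""),
        "[assays] mutation frequency f=%.4g (true %.4g)" % (
            fits["mutfreq"].f, cfg["rif_params"]["f"]),
    ]
    return fits


# ---------------------------------------------------------------------------
# system comparison (wild type vs mutant)
# ---------------------------------------------------------------------------

@dataclass
class SystemComparison:
    delta: energy.DeltaEnergyTable | None
    edges_gained: list[tuple[str, str]]
    edges_lost: list[tuple[str, str]]
    path_wt: network.PathResult | None
    path_mut: network.PathResult | None

    @property
    def path_changed(self) -> bool:
        if self.path_wt is None or self.path_mut is None:
            return False
        return self.path_wt.nodes != self.path_mut.nodes


def compare_systems(result_wt: PipelineResult,
                    result_mut: PipelineResult) -> SystemComparison:
    """Mutant-vs-wild-type differences: per-partner delta-energies,
    edge sets gained/lost, and optimal-path changes."""
    if result_wt.nodes is None or result_mut.nodes is None:
        raise ConfigError("both results need node assignments to compare")
    if result_wt.nodes.labels() != result_mut.nodes.labels():
        raise ConfigError("node sets are incompatible between systems")
    delta = None
    if result_wt.energy_table is not None and result_mut.energy_table is not None:
        delta = energy.delta_energy(result_mut.energy_table,
                                    result_wt.energy_table)

    def edge_set(res: PipelineResult) -> set[tuple[str, str]]:
        if res.net is None:
            return set()
        labels = res.nodes.labels()
        return {
            tuple(sorted((labels[i], labels[j])))
            for i, j in res.net.graph.edges()
        }

    wt_edges, mut_edges = edge_set(result_wt), edge_set(result_mut)
    return SystemComparison(
        delta=delta,
        edges_gained=sorted(mut_edges - wt_edges),
        edges_lost=sorted(wt_edges - mut_edges),
        path_wt=result_wt.path,
        path_mut=result_mut.path,
    )
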