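"""End-to-end orchestration of the riboswitch comparison workflow.

A single declarative YAML config describes the systems (topology +
trajectory files, or a synthetic spec), the analysis parameters and the
output directory. For each system the pipeline emits the full artifact
set — substructure RMSD summary, RMSF profile, hydrogen-bond occupancy
and distance tables, PCA variances/projections, DCCM, contact-filtered
network, centrality profiles, and the k-shortest-path ensemble with node
degeneracy — then compares designated state pairs by SIP, centrality
deltas and DCCM differences. A JSON manifest records the effective
parameters, the seed and input hashes so every number is traceable.

Default parameters are the standard geometric choices for this analysis:
3.5 Å / 30° hydrogen bonds, 4.5 Å / 75% persistent contacts, C5' nodes,
k = 1000 paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError, RibodynError
from .hbonds import HBondCriterion, contact_mask, distance_stats, hbond_occupancy
from .network import (
    build_network,
    centrality_profile,
    compute_dccm,
    sip,
)
from .paths import node_degeneracy, nodes_per_path, path_centrality_summary, yen_k_shortest
from .pca import fit_pca, pc_rmsf, project
from .structure_io import (
    load_annotation,
    read_multimodel_trajectory,
    read_pdb,
    select_atoms,
)
from .superpose import rmsd_series, rmsf_profile
from .synthetic import (
    SyntheticSpec,
    default_annotation,
    make_reference,
    make_trajectory,
    spec_from_manifest,
)

__all__ = ["RunConfig", "run_pipeline", "compare_states", "DEFAULT_PARAMETERS"]

logger = logging.getLogger("ribodyn.pipeline")

DEFAULT_PARAMETERS: dict = {
    "hbond_distance": 3.5,  # Å donor-acceptor
    "hbond_angle": 30.0,  # degrees from D-H-A linearity
    "contact_cutoff": 4.5,  # Å
    "contact_persistence": 0.75,
    "node_selection": "C5'",
    "n_pcs": 3,
    "k_paths": 1000,
    "edge_display_cutoff": 0.6,  # |C| filter for the display edge list only
    "source": None,  # residue labels for path analysis
    "sink": None,
}

_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults resolved."""

    systems: dict
    parameters: dict
    output_dir: str
    seed: int
    comparisons: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str = ".") -> "RunConfig":
        params = dict(DEFAULT_PARAMETERS)
        params.update(raw.get("parameters", {}))
        systems = raw.get("systems")
        if not systems:
            raise PipelineError("config has no systems")
        for name, system in systems.items():
            if "synthetic" in system:
                continue
            for key in ("topology", "trajectory", "annotation"):
                if key not in system:
                    raise PipelineError(f"system {name!r} lacks {key!r}")
                path = os.path.join(base_dir, system[key])
                if not os.path.exists(path):
                    raise PipelineError(f"system {name!r}: missing file {path}")
                system[key] = path
            if "pairs" in system:
                system["pairs"] = os.path.join(base_dir, system["pairs"])
        return cls(
            systems=systems,
            parameters=params,
            output_dir=os.path.join(base_dir, raw.get("output_dir", "ribodyn_out")),
            seed=int(raw.get("seed", 0)),
            comparisons=[tuple(pair) for pair in raw.get("comparisons", [])],
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls.from_dict(raw, base_dir=os.path.dirname(os.path.abspath(path)))


def _write_matrix_csv(matrix: np.ndarray, labels, path: str) -> None:
    frame = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    frame.to_csv(path, float_format=_FLOAT_FORMAT)


def _sha256(path: str) -> str:
    with open(path, "rb") as handle:
        return hashlib.sha256(handle.read()).hexdigest()


def _load_system(name: str, system: dict, config: RunConfig):
    if "synthetic" in system:
        payload = dict(system["synthetic"])
        payload.setdefault("seed", config.seed + sorted(config.systems).index(name))
        spec = spec_from_manifest({"spec": {**_default_spec_payload(), **payload}})
        reference = make_reference(spec)
        trajectory = make_trajectory(reference, spec)
        annotation = default_annotation(spec.n_residues)
        pairs = [
            (tuple(donor), tuple(acceptor))
            for donor, acceptor, _ in spec.hbond_schedule
        ]
        provenance = {"synthetic_seed": spec.seed}
        return reference, trajectory, annotation, pairs, provenance
    reference = read_pdb(system["topology"])
    trajectory = read_multimodel_trajectory(system["trajectory"], reference)
    annotation = load_annotation(system["annotation"], reference)
    pairs = []
    if "pairs" in system:
        with open(system["pairs"]) as handle:
            next(handle)
            for line in handle:
                fields = line.strip().split(",")
                pairs.append(((int(fields[0]), fields[1]), (int(fields[2]), fields[3])))
    provenance = {
        key: _sha256(system[key])
        for key in ("topology", "trajectory", "annotation")
    }
    return reference, trajectory, annotation, pairs, provenance


def _default_spec_payload() -> dict:
    from dataclasses import asdict

    base = asdict(SyntheticSpec())
    base["atom_template"] = [
        [n, e, list(o)] for n, e, o in SyntheticSpec().atom_template
    ]
    base["correlation_blocks"] = []
    base["hbond_schedule"] = []
    return base


def _stage(name: str, out_dir: str):
    """Context-manager-free stage wrapper: call, log, convert errors."""

    def runner(fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except RibodynError as exc:
            with open(os.path.join(out_dir, "FAILED"), "w") as handle:
                handle.write(f"{name}: {exc}\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %-18s %8.2f s", name, time.perf_counter() - start)
        return result

    return runner


def _analyze_system(name: str, system: dict, config: RunConfig) -> dict:
    out_dir = os.path.join(config.output_dir, name)
    os.makedirs(out_dir, exist_ok=True)
    params = config.parameters

    reference, trajectory, annotation, pairs, provenance = _stage("load", out_dir)(
        _load_system, name, system, config
    )

    # Table-1 style RMSD summary over every annotated region
    rows = []
    series_frames = {}
    for region in annotation.names():
        series = _stage(f"rmsd:{region}", out_dir)(
            rmsd_series, trajectory, reference, region, annotation
        )
        rows.append({"region": region, "mean_rmsd": series.mean, "sd_rmsd": series.std})
        series_frames[region] = series.values
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "rmsd_summary.csv"), index=False, float_format=_FLOAT_FORMAT
    )
    pd.DataFrame(series_frames).to_csv(
        os.path.join(out_dir, "rmsd_series.csv"), index_label="frame", float_format=_FLOAT_FORMAT
    )

    heavy = select_atoms(reference, "heavy")
    profile = _stage("rmsf", out_dir)(
        rmsf_profile, trajectory, heavy, heavy, True
    )
    pd.DataFrame(
        {"residue": profile.residue_indices, "rmsf": profile.values}
    ).to_csv(os.path.join(out_dir, "rmsf.csv"), index=False, float_format=_FLOAT_FORMAT)

    criterion = HBondCriterion(params["hbond_distance"], params["hbond_angle"])
    if pairs:
        occ = _stage("hbonds", out_dir)(hbond_occupancy, trajectory, pairs, criterion)
        pd.DataFrame(
            [
                {
                    "donor": rec.donor,
                    "acceptor": rec.acceptor,
                    "frames_observed": rec.frames_observed,
                    "occupancy_percent": rec.occupancy,
                }
                for rec in occ
            ]
        ).to_csv(os.path.join(out_dir, "hbond_occupancy.csv"), index=False, float_format=_FLOAT_FORMAT)
        dist = _stage("distances", out_dir)(distance_stats, trajectory, pairs)
        pd.DataFrame(
            [
                {"atom_a": s.pair[0], "atom_b": s.pair[1], "mean_distance": s.mean, "sd_distance": s.std}
                for s in dist
            ]
        ).to_csv(os.path.join(out_dir, "distance_stats.csv"), index=False, float_format=_FLOAT_FORMAT)

    nodes = select_atoms(reference, params["node_selection"])
    model = _stage("pca", out_dir)(fit_pca, trajectory, nodes)
    n_pcs = int(params["n_pcs"])
    pd.DataFrame(
        {
            "pc": np.arange(1, model.eigenvalues.size + 1),
            "eigenvalue": model.eigenvalues,
            "fractional_variance": model.fractional_variance,
        }
    ).to_csv(os.path.join(out_dir, "pca_variance.csv"), index=False, float_format=_FLOAT_FORMAT)
    projection = project(trajectory, model, list(range(min(n_pcs, model.eigenvalues.size))))
    pd.DataFrame(
        projection.scores, columns=[f"PC{p + 1}" for p in projection.pcs]
    ).to_csv(os.path.join(out_dir, "pca_projection.csv"), index_label="frame", float_format=_FLOAT_FORMAT)
    rmsf_pcs = pc_rmsf(model, list(range(min(n_pcs, model.eigenvalues.size))))
    pd.DataFrame(
        {"residue": reference.residue_indices[nodes.indices], "pc_rmsf": rmsf_pcs}
    ).to_csv(os.path.join(out_dir, "pc_rmsf.csv"), index=False, float_format=_FLOAT_FORMAT)

    mask = _stage("contacts", out_dir)(
        contact_mask, trajectory, params["contact_cutoff"], params["contact_persistence"]
    )
    _write_matrix_csv(mask.mask.astype(int), mask.residue_indices, os.path.join(out_dir, "contact_mask.csv"))

    dccm = _stage("dccm", out_dir)(compute_dccm, trajectory, nodes)
    _write_matrix_csv(dccm.matrix, dccm.labels, os.path.join(out_dir, "dccm.csv"))

    network = _stage("network", out_dir)(build_network, dccm, mask)
    ii, jj = np.nonzero(np.triu(network.adjacency, k=1))
    edges = pd.DataFrame(
        {
            "residue_i": [network.labels[i] for i in ii],
            "residue_j": [network.labels[j] for j in jj],
            "weight": network.weights[ii, jj],
            "abs_correlation": network.strengths[ii, jj],
        }
    )
    edges.to_csv(os.path.join(out_dir, "edges.csv"), index=False, float_format=_FLOAT_FORMAT)
    edges[edges["abs_correlation"] > params["edge_display_cutoff"]].to_csv(
        os.path.join(out_dir, "edges_display.csv"), index=False, float_format=_FLOAT_FORMAT
    )
    with open(os.path.join(out_dir, "network.json"), "w") as handle:
        json.dump(
            {
                "labels": list(network.labels),
                "edges": [
                    [int(network.labels[i]), int(network.labels[j]),
                     float(network.weights[i, j]), float(network.strengths[i, j])]
                    for i, j in zip(ii.tolist(), jj.tolist())
                ],
                "log_base": network.log_base,
            },
            handle,
            indent=2,
        )
        handle.write("\n")

    profile_c = _stage("centrality", out_dir)(centrality_profile, network)
    pd.DataFrame(
        {
            "residue": profile_c.labels,
            "betweenness": profile_c.betweenness,
            "eigenvector": profile_c.eigenvector,
        }
    ).to_csv(os.path.join(out_dir, "centrality.csv"), index=False, float_format=_FLOAT_FORMAT)

    source_label = params["source"] or network.labels[0]
    sink_label = params["sink"] or network.labels[-1]
    ensemble = _stage("paths", out_dir)(
        yen_k_shortest,
        network,
        network.node_index(int(source_label)),
        network.node_index(int(sink_label)),
        int(params["k_paths"]),
    )
    pd.DataFrame(
        {
            "length": ensemble.lengths,
            "nodes": ["-".join(str(network.labels[n]) for n in path) for path in ensemble.paths],
        }
    ).to_csv(os.path.join(out_dir, "paths.csv"), index=False, float_format=_FLOAT_FORMAT)
    if ensemble.k_found:
        degeneracy = node_degeneracy(ensemble, network.n_nodes)
        pd.DataFrame(
            {"residue": network.labels, "degeneracy": degeneracy}
        ).to_csv(os.path.join(out_dir, "degeneracy.csv"), index=False, float_format=_FLOAT_FORMAT)
        summary = {
            "k_requested": ensemble.k_requested,
            "k_found": ensemble.k_found,
            "source": int(source_label),
            "sink": int(sink_label),
            "nodes_per_path": {
                key: value
                for key, value in nodes_per_path(ensemble).items()
                if key != "counts"
            },
            "centrality": path_centrality_summary(ensemble, profile_c),
        }
        with open(os.path.join(out_dir, "path_summary.json"), "w") as handle:
            json.dump(summary, handle, indent=2)
            handle.write("\n")

    return {
        "output_dir": out_dir,
        "provenance": provenance,
        "betweenness": profile_c.betweenness,
        "eigenvector": profile_c.eigenvector,
        "labels": list(network.labels),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis for every system, then the configured
    state-pair comparisons; returns a results dictionary and writes the
    manifest into the output directory."""
    os.makedirs(config.output_dir, exist_ok=True)
    results = {}
    for name in sorted(config.systems):
        results[name] = _analyze_system(name, config.systems[name], config)

    comparisons = {}
    for pair in config.comparisons:
        a, b = pair
        if a not in results or b not in results:
            raise PipelineError(f"comparison names unknown system: {pair}")
        if results[a]["labels"] != results[b]["labels"]:
            raise PipelineError(f"comparison {a} vs {b}: node sets differ")
        comparisons[f"{a}_vs_{b}"] = {
            "sip_betweenness": sip(results[a]["betweenness"], results[b]["betweenness"]),
            "sip_eigenvector": sip(results[a]["eigenvector"], results[b]["eigenvector"]),
        }
    manifest = {
        "ribodyn_version": __version__,
        "seed": config.seed,
        "parameters": config.parameters,
        "systems": {name: results[name]["provenance"] for name in results},
        "comparisons": comparisons,
    }
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return {"systems": results, "comparisons": comparisons, "manifest": manifest}


def compare_states(dir_a: str, dir_b: str, out_dir: str | None = None) -> dict:
    """Compare two completed system output directories.

    Emits the SIP between their betweenness and eigenvector profiles,
    per-node centrality deltas (B minus A), the DCCM difference matrix
    and a degeneracy overlay. Node sets must match.
    """
    cent_a = pd.read_csv(os.path.join(dir_a, "centrality.csv"))
    cent_b = pd.read_csv(os.path.join(dir_b, "centrality.csv"))
    if list(cent_a["residue"]) != list(cent_b["residue"]):
        raise PipelineError("node sets differ between the two bundles")
    dccm_a = pd.read_csv(os.path.join(dir_a, "dccm.csv"), index_col=0)
    dccm_b = pd.read_csv(os.path.join(dir_b, "dccm.csv"), index_col=0)

    report = {
        "sip_betweenness": sip(cent_a["betweenness"].to_numpy(), cent_b["betweenness"].to_numpy()),
        "sip_eigenvector": sip(cent_a["eigenvector"].to_numpy(), cent_b["eigenvector"].to_numpy()),
        "betweenness_delta": (cent_b["betweenness"] - cent_a["betweenness"]).to_numpy(),
        "eigenvector_delta": (cent_b["eigenvector"] - cent_a["eigenvector"]).to_numpy(),
        "dccm_difference": dccm_b.to_numpy() - dccm_a.to_numpy(),
        "residues": cent_a["residue"].to_numpy(),
    }
    deg_path_a = os.path.join(dir_a, "degeneracy.csv")
    deg_path_b = os.path.join(dir_b, "degeneracy.csv")
    if os.path.exists(deg_path_a) and os.path.exists(deg_path_b):
        deg_a = pd.read_csv(deg_path_a)
        deg_b = pd.read_csv(deg_path_b)
        report["degeneracy_a"] = deg_a["degeneracy"].to_numpy()
        report["degeneracy_b"] = deg_b["degeneracy"].to_numpy()

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        pd.DataFrame(
            {
                "residue": report["residues"],
                "betweenness_delta": report["betweenness_delta"],
                "eigenvector_delta": report["eigenvector_delta"],
            }
        ).to_csv(os.path.join(out_dir, "centrality_delta.csv"), index=False, float_format=_FLOAT_FORMAT)
        _write_matrix_csv(
            report["dccm_difference"], report["residues"], os.path.join(out_dir, "dccm_difference.csv")
        )
        with open(os.path.join(out_dir, "comparison.json"), "w") as handle:
            json.dump(
                {
                    "sip_betweenness": report["sip_betweenness"],
                    "sip_eigenvector": report["sip_eigenvector"],
                },
                handle,
                indent=2,
            )
            handle.write("\n")
    return report
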