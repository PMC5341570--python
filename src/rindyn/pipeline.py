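"""Config-driven orchestration of the full analysis pipeline.

This module is the scripting face of the library: a :class:`PipelineConfig`
(loadable from YAML) names the input structure, the atom selections, the
stages to run and their parameters; :func:`run_pipeline` executes the
enabled stages in dependency order (io -> metrics/hbonds/sasa/ss/rcf ->
pca/dccm -> cluster -> rin -> pathway), writes per-stage TSV outputs and a
manifest recording versions, parameters, seed and output checksums.  A thin
console entry point (``rindyn run`` / ``rindyn fixtures``) wraps these two
functions; everything else is meant to be called from Python.

All stage parameters default to the standard analysis values: 0.35 nm / 30
degree hydrogen-bond criteria, 0.5 nm residue-contact cutoff, 0.6 nm atom
contact cutoff, 0.4 nm hydration shell, Jarvis-Patrick M=10 / P=3, 10
eigenvectors for subspace overlap.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import RindynError

__all__ = ["PipelineConfig", "run_pipeline", "generate_fixtures", "main"]

ALL_STAGES = ("metrics", "hbonds", "sasa", "ss", "rcf", "pca", "dccm",
              "cluster", "rin", "pathway")


@dataclass
class PipelineConfig:
    structure: str = ""
    frames: str | None = None
    output_dir: str = "rindyn_out"
    stages: tuple[str, ...] = ALL_STAGES
    selection: str = "protein"
    fit_selection: str = "backbone"
    ca_selection: str = "calpha"
    seed: int = 0
    # stage parameters (standard defaults)
    hbond_distance_nm: float = 0.35
    hbond_angle_deg: float = 30.0
    rin_cutoff_nm: float = 0.5
    contact_cutoff_nm: float = 0.6
    hydration_cutoff_nm: float = 0.4
    sasa_probe_nm: float = 0.14
    sasa_points: int = 960
    dccm_stride: int = 1
    jp_m_neighbors: int = 10
    jp_p_shared: int = 3
    overlap_k: int = 10
    pathway_source: str | None = None   # e.g. "A:299"
    pathway_target_chain: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise RindynError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def validate(self) -> None:
        if self.structure and not Path(self.structure).exists():
            raise RindynError(f"structure file not found: {self.structure}")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise RindynError(f"unknown stages: {sorted(bad)}")
        for name, value in (("hbond_distance_nm", self.hbond_distance_nm),
                            ("rin_cutoff_nm", self.rin_cutoff_nm),
                            ("contact_cutoff_nm", self.contact_cutoff_nm),
                            ("hydration_cutoff_nm", self.hydration_cutoff_nm)):
            if not 0 < value < 5:
                raise RindynError(f"{name} out of documented range (0, 5) nm")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest (also written to disk).

    Stage failures abort with the stage name and cause; outputs written so
    far are preserved.  Identical (config, seed) reruns produce identical
    numeric outputs.
    """
    from . import cluster as cluster_mod
    from . import covariance as cov_mod
    from . import hbond_sasa, metrics, rcf as rcf_mod, rin as rin_mod, secstruct
    from .structure import read_frames, read_structure, select_atoms

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "rindyn",
        "seed": config.seed,
        "parameters": asdict(config),
        "stages_run": [],
        "outputs": {},
        "timings_s": {},
    }
    state: dict = {}

    def record(stage, fname):
        manifest["outputs"][fname] = _sha256(out / fname)

    stage_order = [s for s in ALL_STAGES if s in config.stages]
    if stage_order and not config.structure:
        raise RindynError("config.structure is required when stages are enabled")

    if config.structure:
        topology, traj = read_structure(config.structure)
        if config.frames:
            traj = read_frames(config.frames, topology)
        state["topology"], state["traj"] = topology, traj
        state["sel"] = select_atoms(topology, config.selection)
        state["fit_sel"] = select_atoms(topology, config.fit_selection)
        state["ca_sel"] = select_atoms(topology, config.ca_selection)

    for stage in stage_order:
        t0 = time.perf_counter()
        try:
            _run_stage(stage, config, state, out,
                       metrics=metrics, hbond_sasa=hbond_sasa,
                       secstruct=secstruct, rcf_mod=rcf_mod, cov_mod=cov_mod,
                       cluster_mod=cluster_mod, rin_mod=rin_mod, record=record)
        except Exception as exc:
            raise RindynError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages_run"].append(stage)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(stage, config, state, out, *, metrics, hbond_sasa, secstruct,
               rcf_mod, cov_mod, cluster_mod, rin_mod, record):
    topology, traj = state["topology"], state["traj"]
    sel, fit_sel, ca_sel = state["sel"], state["fit_sel"], state["ca_sel"]

    if stage == "metrics":
        ref = traj.coordinates[0]
        metrics.rmsd_series(traj, ref, fit_sel).to_tsv(out / "rmsd.tsv")
        metrics.radius_of_gyration(traj, sel).to_tsv(out / "rg.tsv")
        if traj.n_frames >= 2:
            values = metrics.rmsf(traj, ca_sel, fit_sel)
            with open(out / "rmsf.tsv", "w") as fh:
                fh.write("# atom\trmsf_nm\n")
                for a, v in zip(ca_sel, values):
                    fh.write(f"{a}\t{v:.6f}\n")
            record(stage, "rmsf.tsv")
        record(stage, "rmsd.tsv")
        record(stage, "rg.tsv")
    elif stage == "hbonds":
        criteria = hbond_sasa.HBondCriteria(config.hbond_distance_nm,
                                            config.hbond_angle_deg)
        series = hbond_sasa.hbond_series(traj, topology, criteria)
        series.to_tsv(out / "hbonds.tsv")
        record(stage, "hbonds.tsv")
    elif stage == "sasa":
        hbond_sasa.sasa_series(traj, sel, config.sasa_probe_nm,
                               config.sasa_points).to_tsv(out / "sasa.tsv")
        record(stage, "sasa.tsv")
    elif stage == "ss":
        counts, matrix = secstruct.ss_timeline(traj, topology)
        counts.to_csv(out / "ss_counts.tsv", sep="\t")
        secstruct.timeline_to_tsv(matrix, out / "ss_timeline.tsv")
        record(stage, "ss_counts.tsv")
        record(stage, "ss_timeline.tsv")
    elif stage == "rcf":
        vectors = rcf_mod.nh_vectors(traj, topology)
        dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
        series = rcf_mod.p2_acf(vectors, dt_ps=dt)
        series.to_tsv(out / "rcf.tsv")
        if series.lags.size >= 10:
            fit = rcf_mod.fit_model_free(series)
            stats = rcf_mod.rotational_stats(fit, series)
            (out / "rcf_fit.json").write_text(json.dumps({
                "a0": fit.a0, "a1_ps": fit.a1, "tau_c_ps": stats.tau_c,
                "d_iso_per_ps": stats.d_iso}, indent=2))
            record(stage, "rcf_fit.json")
        record(stage, "rcf.tsv")
    elif stage == "pca":
        pca = cov_mod.build_pca(traj, ca_sel)
        state["pca"] = pca
        with open(out / "eigenvalues.tsv", "w") as fh:
            fh.write("# component\teigenvalue_nm2\tvariance_fraction\n")
            for i, (ev, fr) in enumerate(zip(pca.eigenvalues,
                                             pca.variance_fractions)):
                fh.write(f"{i + 1}\t{ev:.8g}\t{fr:.6f}\n")
        k = min(3, pca.n_components)
        proj = cov_mod.project(traj, pca, k)
        with open(out / "projections.tsv", "w") as fh:
            fh.write("# frame\t" + "\t".join(f"pc{i+1}" for i in range(k)) + "\n")
            for f in range(proj.shape[0]):
                fh.write(f"{f}\t" + "\t".join(f"{v:.6f}" for v in proj[f]) + "\n")
        cov_mod.porcupine_export(pca, 0, 1.0, topology, out / "porcupine.tsv")
        record(stage, "eigenvalues.tsv")
        record(stage, "projections.tsv")
        record(stage, "porcupine.tsv")
    elif stage == "dccm":
        result = cov_mod.dccm(traj, ca_sel, config.dccm_stride)
        state["dccm"] = result
        result.to_text(out / "dccm.tsv")
        record(stage, "dccm.tsv")
    elif stage == "cluster":
        dist = cluster_mod.rmsd_matrix(traj, ca_sel)
        m = min(config.jp_m_neighbors, traj.n_frames - 1)
        assignment = cluster_mod.jarvis_patrick(dist, m, config.jp_p_shared)
        state["cluster"] = (assignment, dist)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("# frame\tlabel\n")
            for f, lab in enumerate(assignment.labels):
                fh.write(f"{f}\t{lab}\n")
        with open(out / "cluster_summary.tsv", "w") as fh:
            fh.write("# label\tsize\trepresentative_frame\n")
            for lab in range(assignment.n_clusters):
                rep = cluster_mod.representative(assignment, dist, lab)
                fh.write(f"{lab}\t{assignment.sizes[lab]}\t{rep}\n")
        record(stage, "clusters.tsv")
        record(stage, "cluster_summary.tsv")
    elif stage == "rin":
        if "cluster" in state:
            assignment, dist = state["cluster"]
            biggest = int(np.argmax(assignment.sizes))
            frame_idx = cluster_mod.representative(assignment, dist, biggest)
        else:
            frame_idx = 0
        graph = rin_mod.build_rin(traj.coordinates[frame_idx], topology,
                                  config.rin_cutoff_nm)
        if "dccm" in state:
            rin_mod.annotate_strengths(graph, state["dccm"], topology)
        state["rin"] = graph
        rin_mod.topology_stats(graph).to_tsv(out / "rin_stats.tsv")
        rin_mod.edges_to_tsv(graph, out / "rin_edges.tsv")
        if graph.number_of_nodes() >= 3:
            rin_mod.centralities(graph).to_tsv(out / "rin_centrality.tsv")
            record(stage, "rin_centrality.tsv")
        partition = rin_mod.girvan_newman(graph)
        with open(out / "rin_communities.tsv", "w") as fh:
            fh.write(f"# communities={partition.n_communities} "
                     f"integrated={partition.n_integrated} "
                     f"isolated={partition.n_isolated} "
                     f"modularity={partition.modularity:.4f}\n")
            for node in sorted(partition.labels):
                fh.write(f"{node}\t{partition.labels[node]}\n")
        record(stage, "rin_stats.tsv")
        record(stage, "rin_edges.tsv")
        record(stage, "rin_communities.tsv")
    elif stage == "pathway":
        if config.pathway_source is None or config.pathway_target_chain is None:
            raise RindynError("pathway stage needs pathway_source and "
                              "pathway_target_chain")
        graph = state.get("rin")
        if graph is None:
            raise RindynError("pathway stage requires the rin stage")
        pathway = rin_mod.interface_pathway(graph, config.pathway_source,
                                            config.pathway_target_chain)
        with open(out / "pathway.tsv", "w") as fh:
            fh.write(f"# source={pathway.source} target_chain="
                     f"{pathway.target_chain} n_nodes={pathway.n_nodes} "
                     f"n_edges={pathway.n_edges} "
                     f"terminated={pathway.terminated}\n")
            fh.write("# bridging pairs: " + "; ".join(
                "-".join(sorted(e)) for e in sorted(
                    pathway.bridging_pairs, key=lambda e: sorted(e))) + "\n")
            for node in sorted(pathway.nodes):
                fh.write(f"{node}\n")
        record(stage, "pathway.tsv")


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("gaussian", "rotdiff", "helix", "sheet", "coil", "toy_complex",
                 "multistate", "hbond")


def generate_fixtures(kind: str, parameters: dict | None = None, seed: int = 0,
                      output_dir: str = "fixtures") -> dict:
    """Write a synthetic fixture (PDB + plain-text frames + ground truth).

    ``kind`` is one of ``gaussian``, ``rotdiff``, ``helix``, ``sheet``,
    ``coil``, ``toy_complex``, ``multistate``, ``hbond``; unknown kinds
    raise an error listing the available ones.  Same (kind, parameters,
    seed) -> identical files.
    """
    from . import synth
    from .structure import write_frames, write_structure

    p = dict(parameters or {})
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"kind": kind, "seed": seed, "parameters": p}
    if kind == "gaussian":
        n_atoms = int(p.get("n_atoms", 10))
        rng = np.random.default_rng(seed)
        ref = rng.standard_normal((n_atoms, 3))
        mode = rng.standard_normal(3 * n_atoms)
        mode /= np.linalg.norm(mode)
        spec = synth.GaussianTrajSpec(
            reference=ref, modes=mode[None, :],
            mode_variances=np.array([p.get("mode_variance", 1.0)]),
            noise_variance=p.get("noise_variance", 0.01),
            n_frames=int(p.get("n_frames", 2000)), seed=seed)
        traj = synth.gen_gaussian_traj(spec)
        truth["planted_mode"] = mode.tolist()
    elif kind == "rotdiff":
        # rigid amide group (C, N, H) so the NH-vector machinery applies
        template = np.array([[0.0, 0.0, 0.0], [0.13, 0.0, 0.0],
                             [0.17, 0.093, 0.0]])
        spec = synth.RotDiffSpec(template=template,
                                 diffusion_constant=p.get("d", 1e-4),
                                 n_frames=int(p.get("n_frames", 20000)),
                                 dt_ps=p.get("dt_ps", 1.0), seed=seed)
        traj = synth.gen_rotational_diffusion(spec)
        from .structure import Trajectory
        records = [("A", 1, "GLY", [("C", "C", template[0])]),
                   ("A", 2, "GLY", [("N", "N", template[1]),
                                    ("H", "H", template[2])])]
        top, _ = synth._build_topology(records)
        traj = Trajectory(traj.coordinates, traj.times, top)
        truth["expected_tau_c_ps"] = 1.0 / (6.0 * spec.diffusion_constant)
    elif kind in ("helix", "sheet", "coil"):
        kinds = {"helix": "alpha_helix", "sheet": "antiparallel_sheet",
                 "coil": "extended_coil"}
        _, traj = synth.gen_ideal_secondary(kinds[kind], int(p.get("n_residues", 12)))
    elif kind == "toy_complex":
        spec = synth.ToyComplexSpec(
            chain_sizes=tuple(p.get("chain_sizes", (20, 20))),
            bridges=[tuple(map(tuple, b)) for b in p.get("bridges", [[(0, 10), (1, 10)]])],
            layout=p.get("layout", "line"), seed=seed)
        _, traj = synth.gen_toy_complex(spec)
        truth["bridges"] = [list(map(list, b)) for b in spec.bridges]
    elif kind == "multistate":
        traj, labels = synth.gen_multistate_traj(
            k=int(p.get("k", 2)), per_state_frames=int(p.get("per_state_frames", 30)),
            intra_spread=p.get("intra_spread", 0.01),
            inter_state_rmsd=p.get("inter_state_rmsd", 1.0), seed=seed)
        truth["labels"] = labels.tolist()
    elif kind == "hbond":
        _, traj = synth.gen_hbond_fixture(p.get("distance", 0.30),
                                          p.get("angle", 10.0))
    else:
        raise RindynError(f"unknown fixture kind {kind!r}; "
                          f"available: {', '.join(FIXTURE_KINDS)}")
    pdb_path = out / f"{kind}.pdb"
    frames_path = out / f"{kind}.frames"
    write_structure(pdb_path, traj.topology, traj.slice_frames(0, 1))
    write_frames(frames_path, traj)
    truth_path = out / f"{kind}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {"pdb": str(pdb_path), "frames": str(frames_path),
            "truth": str(truth_path)}


# ---------------------------------------------------------------------------
# Console entry point
# ---------------------------------------------------------------------------

def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        prog="rindyn",
        description="Protein-dynamics post-analysis pipeline")
    sub = parser.add_subparsers(dest="command", required=True)
    run_p = sub.add_parser("run", help="run the pipeline from a YAML config")
    run_p.add_argument("config", help="YAML pipeline configuration")
    fix_p = sub.add_parser("fixtures", help="generate a synthetic fixture")
    fix_p.add_argument("kind", help=f"one of: {', '.join(FIXTURE_KINDS)}")
    fix_p.add_argument("--seed", type=int, default=0)
    fix_p.add_argument("--out", default="fixtures")
    args = parser.parse_args(argv)
    try:
        if args.command == "run":
            manifest = run_pipeline(PipelineConfig.from_yaml(args.config))
            print(json.dumps({"stages_run": manifest["stages_run"],
                              "outputs": sorted(manifest["outputs"])}, indent=2))
        else:
            paths = generate_fixtures(args.kind, seed=args.seed,
                                      output_dir=args.out)
            print(json.dumps(paths, indent=2))
    except RindynError as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
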