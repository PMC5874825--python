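"""End-to-end orchestration: config file, stages, reports, CLI.

Stages are independently useful and independently runnable:

* ``simulate``  — write the synthetic inputs (trajectories + topology
  sidecars) to disk;
* ``solvation`` — RDF/coordination/H-bond/hydration-shell report for a
  single-solute trajectory;
* ``search``    — random dimer search on the toy energy landscape;
* ``thermo``    — standard-state and association free-energy arithmetic
  (replays a user-supplied component table when given);
* ``pim``       — pair counting, three-body reduction and the pairwise
  interaction matrix for a mixed-species trajectory;
* ``all``       — everything above.

Identical config + seed gives byte-identical outputs.  The seed is
recorded in every summary.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import aggregation, cluster_search, solvation, synthetic, thermo
from .constants import (CONTACT_CUTOFF, DEFAULT_TEMPERATURE, HBOND_CUTOFF,
                        RTILDE)
from .topology import Trajectory, read_trajectory, write_topology, \
    write_trajectory

__all__ = ["RunConfig", "run_pipeline", "main"]

log = logging.getLogger("solvagg")

STAGES = ("solvation", "search", "thermo", "pim")


@dataclass
class RunConfig:
    """Every numeric default of the pipeline, surfaced in one place.

    ``trajectory``/``mixture_trajectory`` point at input files; when
    absent the corresponding synthetic generator runs instead with the
    parameters below.
    """

    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    rtilde: float = RTILDE
    hbond_cutoff: float = HBOND_CUTOFF
    contact_cutoff: float = CONTACT_CUTOFF
    bin_width: float = 0.02
    search_from: float = 1.2
    shell_radius: float = 4.5
    last_ns: float | None = None
    format: str = "xyz-ext"
    out_dir: str = "solvagg_out"

    trajectory: str | None = None
    mixture_trajectory: str | None = None
    components_table: str | None = None

    # synthetic solvated-solute box
    n_waters: int = 80
    solvated_box: float = 14.0
    donor_contact_prob: float = 0.6
    solvation_frames: int = 100
    solute_species: str = "nonionic"

    # synthetic mixed box
    n_nonionic: int = 10
    n_zwitterionic: int = 10
    mixture_box: float = 50.0
    mixture_frames: int = 100
    pair_frequencies: dict = field(
        default_factory=lambda: {"nn": 2.0, "zz": 3.0, "mixed": 1.0})

    # cluster search
    n_candidates: int = 2000
    cube_side: float = 14.0
    grid_spacing: float = 1.0

    def __post_init__(self) -> None:
        for name in ("hbond_cutoff", "contact_cutoff", "bin_width",
                     "shell_radius", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- round-trippable serialisation ------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _solvated_trajectory(cfg: RunConfig) -> Trajectory:
    if cfg.trajectory:
        return read_trajectory(cfg.trajectory, format=cfg.format)
    return synthetic.make_solvated_solute(
        n_waters=cfg.n_waters, box=cfg.solvated_box,
        donor_contact_prob=cfg.donor_contact_prob,
        n_frames=cfg.solvation_frames, seed=cfg.seed,
        species=cfg.solute_species)


def _mixture_trajectory(cfg: RunConfig) -> Trajectory:
    if cfg.mixture_trajectory:
        return read_trajectory(cfg.mixture_trajectory, format=cfg.format)
    spec = synthetic.PlantedMixtureSpec(
        n_nonionic=cfg.n_nonionic, n_zwitterionic=cfg.n_zwitterionic,
        box=cfg.mixture_box, n_frames=cfg.mixture_frames,
        pair_frequencies=dict(cfg.pair_frequencies), seed=cfg.seed + 1)
    return synthetic.make_planted_mixture(spec).trajectory


def _window(traj: Trajectory, cfg: RunConfig) -> Trajectory:
    if cfg.last_ns is None:
        return traj
    return traj.last_window(cfg.last_ns * 1000.0)


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    traj = _solvated_trajectory(cfg)
    ext = "gro" if cfg.format == "gro" else "xyz"
    p1 = out / f"solvated.{ext}"
    write_trajectory(traj, p1, format=cfg.format)
    write_topology(traj.topology,
                   p1.with_name(p1.name + ".topology.yaml"))
    mix = _mixture_trajectory(cfg)
    p2 = out / f"mixture.{ext}"
    write_trajectory(mix, p2, format=cfg.format)
    write_topology(mix.topology, p2.with_name(p2.name + ".topology.yaml"))
    return {"solvated_file": p1.name, "solvated_frames": len(traj),
            "mixture_file": p2.name, "mixture_frames": len(mix)}


def stage_solvation(cfg: RunConfig, out: Path) -> dict:
    traj = _window(_solvated_trajectory(cfg), cfg)
    top = traj.topology
    summary: dict = {"frames": len(traj)}
    for pair, (lab_x, lab_h) in {"Om-Hw": ("Om", "Hw"),
                                 "Nm-Hw": ("Nm", "Hw")}.items():
        sel_x = top.select(label=lab_x)
        sel_h = top.select(label=lab_h, species="water")
        if sel_x.size == 0:
            continue
        rdf = solvation.compute_rdf(traj, sel_x, sel_h,
                                    bin_width=cfg.bin_width,
                                    labels=(lab_x, lab_h))
        n_curve = solvation.running_coordination_number(rdf)
        _write_tsv(out / f"rdf_{pair}.tsv", ("r_A", "g", "n"),
                   np.column_stack([rdf.r, rdf.g, n_curve]))
        row = {}
        try:
            pk = solvation.first_peak_metrics(rdf,
                                              search_from=cfg.search_from)
            row = {f"rmax{pair}": round(pk.r_max, 3),
                   f"gmax{pair}": round(pk.g_max, 3),
                   f"rmin{pair}": round(pk.r_min, 3),
                   f"gmin{pair}": round(pk.g_min, 3),
                   f"ratio{pair}": (round(solvation.peak_ratio(pk), 3)
                                    if pk.g_min > 0 else "inf"),
                   f"nw{pair}": round(pk.n_w, 3)}
        except solvation.NoPeakError:
            row = {f"peak{pair}": "none"}
        hb = solvation.hbond_series(traj, sel_x, sel_h,
                                    cutoff=cfg.hbond_cutoff)
        row[f"hbond_fraction_{pair}"] = round(float(hb.mean()), 4)
        summary.update(row)

    solute_mol = top.solute_molecules()[0]
    hs = solvation.hydration_shell_distribution(traj, solute_mol,
                                                cfg.shell_radius)
    summary["hydration_mean"] = round(hs.mean, 3)
    summary["hydration_mad"] = round(hs.mad, 3)
    _write_tsv(out / "hydration_distribution.tsv", ("n_waters", "p"),
               np.column_stack([np.arange(hs.distribution.size),
                                hs.distribution]))
    _write_report(out / "solvation_report.tsv", summary)
    return summary


def stage_search(cfg: RunConfig, out: Path) -> dict:
    central = synthetic.solute_fragment("nonionic")
    mobile = synthetic.solute_fragment("zwitterionic")
    pot = synthetic.toy_potential_for([central, mobile])
    cands = cluster_search.generate_candidates(
        central, mobile, cube_side=cfg.cube_side, n=cfg.n_candidates,
        seed=cfg.seed + 2)
    kept = cluster_search.contact_filter(cands, cutoff=cfg.contact_cutoff)
    cluster_search.evaluate_energies(kept,
                                     cluster_search.toy_dimer_oracle(pot))
    ranked = cluster_search.boltzmann_rank(kept, T=cfg.temperature)
    rule = cluster_search.SelectionRule(seed=cfg.seed + 3)
    selected = cluster_search.select_for_refinement(ranked, rule)
    _export_candidates(out / "candidates.xyz", central, mobile,
                       ranked[:100])
    _export_selection(out / "selection.tsv", ranked, selected)
    e0 = ranked[0].energy
    return {"generated": len(cands), "after_contact_filter": len(kept),
            "selected": len(selected),
            "best_energy_kcal_mol": round(e0, 6),
            "best_weight": round(ranked[0].weight, 6)}


def stage_thermo(cfg: RunConfig, out: Path) -> dict:
    summary = {"standard_state_correction_kcal_mol":
               round(thermo.standard_state_correction(cfg.temperature,
                                                      cfg.rtilde), 4)}
    if cfg.components_table:
        species = thermo.read_component_table(cfg.components_table,
                                              temperature=cfg.temperature)
        averaged = {}
        for name, comps in species.items():
            gs = np.array([thermo.free_energy(c) for c in comps])
            ens = thermo.IsomerEnsemble(gs, temperature=cfg.temperature)
            averaged[name] = thermo.boltzmann_average(ens)
        results = []
        monomers = [n for n in averaged if "+" not in n and "(" not in n]
        for name, g in averaged.items():
            if name in monomers:
                continue
            # dimer rows are named "A+B" in the table
            parts = name.split("+")
            if len(parts) == 2 and all(p in averaged for p in parts):
                dg = thermo.association_free_energy(
                    g, averaged[parts[0]], averaged[parts[1]])
                results.append(thermo.AssociationResult(
                    reaction=f"{parts[0]} + {parts[1]} -> {name}",
                    route=species[name][0].route, dG_ass=dg))
        if results:
            thermo.association_report(results).to_csv(
                out / "association.tsv", sep="\t", index=False)
            summary["reactions"] = {r.reaction: round(r.dG_ass, 4)
                                    for r in results}
    else:
        planted = synthetic.make_isomer_ensemble(
            12, energy_spacing=0.75, seed=cfg.seed + 4,
            temperature=cfg.temperature)
        summary["demo_ensemble_average_kcal_mol"] = round(
            thermo.boltzmann_average(planted.ensemble), 6)
        summary["demo_ensemble_min_weight_gap"] = round(
            float(planted.weights[0] - planted.weights[1]), 6)
    _write_report(out / "thermo_report.tsv", summary, flatten=True)
    return summary


def stage_pim(cfg: RunConfig, out: Path) -> dict:
    traj = _window(_mixture_trajectory(cfg), cfg)
    pairs = aggregation.count_species_pairs(traj,
                                            cutoff=cfg.contact_cutoff)
    pairs.to_frame().to_csv(out / "pair_counts.tsv", sep="\t", index=False)
    frames3 = aggregation.reduce_three_body(traj)
    pim = aggregation.pairwise_interaction_matrix(
        frames3, cutoff=cfg.contact_cutoff)
    summary = {"frames": len(traj),
               "mean_pairs": {"nn": round(float(pairs.nn.mean()), 4),
                              "zz": round(float(pairs.zz.mean()), 4),
                              "mixed": round(float(pairs.mixed.mean()), 4)},
               "pim_defined": not pim.undefined}
    if not pim.undefined:
        pim.to_frame().round(1).to_csv(out / "pim_percent.tsv", sep="\t")
        summary["pim_percent_upper_sum"] = round(
            float(np.triu(pim.percent).sum()), 4)
    else:
        pim.to_frame(percent=False).to_csv(out / "pim_raw.tsv", sep="\t")
    return summary


_STAGE_FN = {"simulate": stage_simulate, "solvation": stage_solvation,
             "search": stage_search, "thermo": stage_thermo,
             "pim": stage_pim}


def run_pipeline(config: RunConfig,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages; write per-stage outputs plus a
    machine-readable ``summary.json`` under ``config.out_dir``.

    A stage failure is logged with the stage name and re-raised after
    the partial summary has been written (partial outputs preserved).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed, "stages": {}}
    try:
        for stage in stages:
            if stage not in _STAGE_FN:
                raise ValueError(f"unknown stage {stage!r}")
            log.info("running stage %s", stage)
            summary["stages"][stage] = _STAGE_FN[stage](config, out)
    except Exception:
        log.exception("stage %s failed", stage)
        _write_summary(out / "summary.json", summary)
        raise
    _write_summary(out / "summary.json", summary)
    return summary


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _write_tsv(path: Path, header: tuple[str, ...], table: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in table:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def _write_report(path: Path, summary: dict, flatten: bool = False) -> None:
    with open(path, "w") as fh:
        for k, v in summary.items():
            if isinstance(v, dict):
                for k2, v2 in v.items():
                    fh.write(f"{k}.{k2}\t{v2}\n")
            else:
                fh.write(f"{k}\t{v}\n")


def _write_summary(path: Path, summary: dict) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _export_candidates(path: Path, central, mobile, ranked) -> None:
    """Multi-structure extended XYZ with energy/weight in the comment."""
    elements = list(central.elements) + list(mobile.elements)
    with open(path, "w") as fh:
        for c in ranked:
            xyz = c.coordinates
            fh.write(f"{len(elements)}\n")
            fh.write(f"candidate={c.index} E_kcal_mol={c.energy:.6f} "
                     f"weight={c.weight:.6e}\n")
            for el, p in zip(elements, xyz):
                fh.write(f"{el:<3s} {p[0]:12.6f} {p[1]:12.6f} "
                         f"{p[2]:12.6f}\n")


def _export_selection(path: Path, ranked, selected) -> None:
    chosen = {id(c) for c in selected}
    e0 = ranked[0].energy
    with open(path, "w") as fh:
        fh.write("index\tdE_kcal_mol\tf_i\tselected\n")
        for c in ranked:
            fh.write(f"{c.index}\t{c.energy - e0:.6f}\t{c.weight:.6e}\t"
                     f"{int(id(c) in chosen)}\n")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="solvagg",
        description="Solvation and aggregation analysis of tautomeric "
                    "solutes (RDF metrics, dimer search, association "
                    "thermodynamics, pairwise interaction matrices).")
    p.add_argument("stage", choices=list(_STAGE_FN) + ["all"],
                   help="pipeline stage to run")
    p.add_argument("--config", type=Path, help="YAML config file")
    p.add_argument("--seed", type=int, help="master random seed")
    p.add_argument("--cutoff", type=float, dest="contact_cutoff",
                   help="contact cutoff in Å")
    p.add_argument("--temperature", type=float, help="temperature in K")
    p.add_argument("--bin-width", type=float, dest="bin_width",
                   help="RDF bin width in Å")
    p.add_argument("--last-ns", type=float, dest="last_ns",
                   help="restrict analysis to the last N ns")
    p.add_argument("--format", choices=["xyz-ext", "gro"],
                   help="trajectory dialect (files use xyz/gro suffixes)")
    p.add_argument("--out", dest="out_dir", help="output directory")
    p.add_argument("-v", "--verbose", action="store_true")
    return p


def main(argv: list[str] | None = None) -> int:
    args = _build_parser().parse_args(argv)
    logging.basicConfig(
        level=logging.DEBUG if args.verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s")
    cfg = (RunConfig.from_yaml(args.config) if args.config else RunConfig())
    for name in ("seed", "contact_cutoff", "temperature", "bin_width",
                 "last_ns", "format", "out_dir"):
        val = getattr(args, name, None)
        if val is not None:
            setattr(cfg, name, val)
    stages = STAGES if args.stage == "all" else (args.stage,)
    try:
        run_pipeline(cfg, stages=stages)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        log.error("pipeline failed: %s", exc)
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
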