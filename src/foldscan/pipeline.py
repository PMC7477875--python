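"""End-to-end orchestration: stats → ADM → F value → conservation → Gō.

A single :class:`RunConfig` (round-trippable through YAML) drives the
stages in dependency order; every stochastic stage carries an explicit
seed and all parameter defaults mirror the analysis protocol (10 runs ×
60,000 F-value steps; 10⁵ equilibration + 10⁶ production Gō steps with
exchanges every 100; density constant C = 36.12; a_Θ = 0.6π; thresholds
90% / 70% / 5 Å / ±5 residues / k ≥ 16).  Each stage writes its outputs
plus a JSON manifest with versions, seeds, parameters and input
checksums, so any stage can be re-run bit-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, adm, conservation, fvalue, go_model, stats, synthetic, wham

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "foldscan_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["adm", "fvalue"])
    # inputs
    fasta: str | None = None
    stats_tsv: str | None = None
    pdb: str | None = None
    msa: str | None = None
    # synthetic fallback inputs
    planted_length: int = 70
    planted_blocks: list[tuple[int, int]] = field(default_factory=lambda: [(5, 25), (40, 60)])
    planted_hub: int | None = None
    # stats stage
    min_count: int = 10
    # adm stage
    density_C: float = adm.DENSITY_C
    adm_D: float | None = None
    # fvalue stage
    fvalue_runs: int = 10
    fvalue_steps: int = 60000
    contact_cutoff: float = fvalue.DEFAULT_CONTACT_CUTOFF
    # go stage
    go_tmin: float = 0.84
    go_tmax: float = 1.00
    go_ntemps: int = 32
    go_equil: int = 100_000
    go_prod: int = 1_000_000
    go_exchange: int = 100
    go_record: int = 10
    # conservation stage
    chr_threshold: float = 0.9
    region_threshold: float = 0.7
    packing_cutoff: float = 5.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["planted_blocks"] = [tuple(b) for b in data.get("planted_blocks", [])]
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the manifest dict.

    Partial failure leaves completed stage outputs on disk; a stage whose
    dependency output is missing raises an actionable error naming it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "foldscan_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
        "conventions": {
            "scan_profiles": "dv=rho(a<b<=i)-rho(a<=i<b); dh=rho(i<=a<b)-rho(a<i<=b)",
            "coordinates": "1-based inclusive residue indices",
        },
    }
    for key in ("fasta", "stats_tsv", "pdb", "msa"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}

    table = None
    sequence = None
    if config.stats_tsv:
        table = stats.DistanceStatistics.from_tsv(config.stats_tsv)
    if config.fasta:
        from Bio import SeqIO
        rec = next(SeqIO.parse(config.fasta, "fasta"))
        sequence = str(rec.seq).upper()
    if table is None or sequence is None:
        spec = synthetic.PlantedSpec(length=config.planted_length,
                                     seed=config.seed,
                                     blocks=list(config.planted_blocks),
                                     hub_position=config.planted_hub)
        seq_p, table_p = synthetic.make_planted_stats(spec)
        table = table if table is not None else table_p
        sequence = sequence if sequence is not None else seq_p
        manifest["inputs"]["planted"] = dataclasses.asdict(spec)

    regions = None
    fprof = None
    for stage in config.stages:
        if stage == "stats":
            if not config.pdb:
                corpus = synthetic.make_corpus(20, 60, config.seed)
            else:
                raise NotImplementedError(
                    "stats stage over a PDB directory runs via the CLI "
                    "(foldscan stats build)")
            table = stats.collect_statistics(corpus, min_count=config.min_count)
            table.to_tsv(out / "stats.tsv")
            manifest["stages"]["stats"] = {"entries": table.n_entries()}
        elif stage == "adm":
            amap, profiles, regions = adm.analyze_sequence(
                sequence, table, D=config.adm_D, C=config.density_C)
            amap.to_edge_tsv(out / "adm_map.tsv")
            with open(out / "adm_profiles.tsv", "w") as fh:
                fh.write("residue\tdelta_rho_v\tdelta_rho_h\n")
                for i, (v, h) in enumerate(zip(profiles.delta_rho_v,
                                               profiles.delta_rho_h), start=1):
                    fh.write(f"{i}\t{v:.6f}\t{h:.6f}\n")
            with open(out / "adm_regions.json", "w") as fh:
                json.dump([r.as_dict() for r in regions], fh, indent=1)
            manifest["stages"]["adm"] = {
                "D": amap.D, "density": amap.density,
                "n_regions": len(regions),
                "delta_rho_convention": manifest["conventions"]["scan_profiles"],
            }
        elif stage == "fvalue":
            fprof = fvalue.analyze(sequence, table,
                                   n_runs=config.fvalue_runs,
                                   n_steps=config.fvalue_steps,
                                   contact_cutoff=config.contact_cutoff,
                                   seed=config.seed)
            with open(out / "fvalue_profile.tsv", "w") as fh:
                fh.write("residue\tF\n")
                for i, v in enumerate(fprof.f, start=1):
                    fh.write(f"{i}\t{v:.6f}\n")
            with open(out / "fvalue_peaks.json", "w") as fh:
                json.dump({"F_cut": fprof.f_cut, "kT": fprof.kT,
                           "peaks": fprof.peaks}, fh, indent=1)
            np.savetxt(out / "fvalue_Q.tsv", fprof.q_matrix,
                       delimiter="\t", fmt="%.6f")
            manifest["stages"]["fvalue"] = {"kT": fprof.kT,
                                            "F_cut": fprof.f_cut,
                                            "n_peaks": len(fprof.peaks)}
        elif stage == "go":
            if config.pdb:
                from .structure import read_pdb
                st = read_pdb(config.pdb)
            else:
                st = synthetic.make_mini_native("hairpin", 24, seed=config.seed)
            top = go_model.extract_topology(st)
            top.to_json(out / "go_topology.json")
            ladder = go_model.temperature_ladder(config.go_tmin, config.go_tmax,
                                                 config.go_ntemps)
            traj = go_model.replica_exchange(
                top, ladder, equil_steps=config.go_equil,
                prod_steps=config.go_prod,
                exchange_interval=config.go_exchange,
                record_interval=config.go_record, seed=config.seed)
            traj.to_tsv(out / "go_trajectory.tsv")
            res = wham.wham_analysis(ladder, traj.energies, traj.q_values,
                                     query_temps=[float(ladder[0]),
                                                  float(ladder[-1])])
            res.free_energy_tsv(out / "go_free_energy.tsv")
            res.heat_capacity_tsv(out / "go_heat_capacity.tsv")
            manifest["stages"]["go"] = {"n_contacts": top.n_contacts,
                                        "T_f": res.t_f,
                                        "exchange_acceptance":
                                        traj.exchange_accepts / max(traj.exchange_attempts, 1)}
        elif stage == "conservation":
            if not config.msa:
                raise FileNotFoundError(
                    "conservation stage needs an alignment; set config.msa "
                    "(produced by e.g. `foldscan synth msa`)")
            msa = conservation.read_alignment(config.msa)
            sites = conservation.find_chr(msa, threshold=config.chr_threshold)
            with open(out / "chr_sites.tsv", "w") as fh:
                fh.write("site\tfraction\n")
                for s in sites:
                    fh.write(f"{s.site}\t{s.fraction:.3f}\n")
            manifest["stages"]["conservation"] = {"n_chr": len(sites)}
        else:
            raise ValueError(f"unknown stage: {stage}")

    if regions is not None and fprof is not None:
        overlap = compare_fvalue_adm(fprof, regions)
        with open(out / "fvalue_adm_overlap.json", "w") as fh:
            json.dump(overlap, fh, indent=1)
        manifest["stages"]["overlap"] = {"n_peaks": len(overlap)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def compare_fvalue_adm(fprofile: fvalue.FValueProfile, regions,
                       chr_residues: dict[str, int] | None = None,
                       window: int = 5) -> list[dict]:
    """Cross-method synthesis: for each F-value peak, the CHRs within
    ± ``window`` residues and the compact regions containing or adjacent
    to the peak.  All inputs must share one residue coordinate system."""
    n = len(fprofile.f)
    out = []
    for pk in fprofile.peaks:
        p = pk["peak"]
        if p > n:
            raise ValueError("peak index outside the F profile: "
                             "coordinate systems disagree")
        near_chr = {}
        if chr_residues:
            near_chr = {lab: r for lab, r in chr_residues.items()
                        if r is not None and abs(r - p) <= window}
        containing = [r.as_dict() for r in regions if r.start <= p <= r.end]
        adjacent = [r.as_dict() for r in regions
                    if not (r.start <= p <= r.end)
                    and min(abs(r.start - p), abs(r.end - p)) <= window]
        out.append({"peak": p, "chr_within_window": near_chr,
                    "regions_containing": containing,
                    "regions_adjacent": adjacent})
    return out
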