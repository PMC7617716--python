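"""Orchestration: fixtures -> conformer clustering -> complex enumeration ->
per-complex analyses -> pooled reports.

A :class:`RunManifest` enumerates the Cartesian product of G-quadruplex specs
and peptide conformers (gq-major, stable ordering).  Each job plants one
conformer against one GQ in a designated pose, generates a short
pseudo-trajectory (optionally with progressive strand displacement to emulate
quartet destabilization), and scores quartet integrity, binding modes and
contacts.  Pooled per-GQ outputs are merged contact maps, occupancy grids,
summed mode matrices and the stability scatter table.  Jobs are isolated: a
failure is logged into a failure table without aborting the run, and completed
jobs are skipped on resume.  Every TSV carries the manifest hash so outputs
can be traced to their exact parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfg
from .clustering import cluster as cluster_conformers, featurize, representatives
from .contacts import ContactMap, contact_map, merge_maps
from .errors import GQKitError
from .hbonds import (
    HBondCriterion,
    StabilitySeries,
    detect_quartets,
    quartet_hbond_series,
    stability_scatter,
)
from .modes import MODES, interaction_matrix
from .occupancy import occupancy_grid, write_dx
from .structures import Ensemble, write_structure
from .synthetic import (
    DEFAULT_PEPTIDE_SEQUENCE,
    GQSpec,
    PoseSpec,
    build_gq,
    make_peptide_conformers,
    make_unfolding_trajectory,
    place_peptide,
)

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "Job", "enumerate_complexes", "run_all"]


@dataclass(frozen=True)
class Job:
    gq_id: str
    conformer_id: int
    pose_mode: str
    unstable: bool
    seed: int

    @property
    def name(self) -> str:
        return f"{self.gq_id}_c{self.conformer_id:03d}"


@dataclass
class RunManifest:
    """Inputs, thresholds and seeds of one pipeline run."""

    gq_specs: dict[str, GQSpec] = field(
        default_factory=lambda: {"gq_tet_dna": GQSpec(n_strands=4, nucleic_kind="DNA")}
    )
    peptide_sequence: str = DEFAULT_PEPTIDE_SEQUENCE
    n_conformers: int = 5
    n_frames: int = 12
    noise_sigma: float = 0.08
    unstable_displacement: float = 0.8
    unstable_jobs: tuple[int, ...] = ()      # flat job indices planted as unstable
    pose_cycle: tuple[str, ...] = ("end_stack", "groove", "loop")
    anchor_residue_index: int = 26           # peptide residue anchored in the pose
    seed: int = 0
    config: cfg.PipelineConfig = field(default_factory=cfg.PipelineConfig)

    def digest(self) -> str:
        payload = {
            "gq_specs": {k: asdict(v) for k, v in sorted(self.gq_specs.items())},
            "peptide_sequence": self.peptide_sequence,
            "n_conformers": self.n_conformers,
            "n_frames": self.n_frames,
            "noise_sigma": self.noise_sigma,
            "unstable_displacement": self.unstable_displacement,
            "unstable_jobs": list(self.unstable_jobs),
            "pose_cycle": list(self.pose_cycle),
            "anchor_residue_index": self.anchor_residue_index,
            "seed": self.seed,
            "config": {
                k: (sorted(v) if isinstance(v, frozenset) else v)
                for k, v in asdict(self.config).items()
            },
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def enumerate_complexes(manifest: RunManifest) -> list[Job]:
    """Cartesian product of GQ specs and conformers, gq-major stable order."""
    if not manifest.gq_specs:
        raise GQKitError("manifest lists no GQ specs")
    if manifest.n_conformers < 1:
        raise GQKitError("manifest lists no conformers")
    jobs: list[Job] = []
    flat = 0
    for gq_id in manifest.gq_specs:
        for c in range(manifest.n_conformers):
            jobs.append(
                Job(
                    gq_id=gq_id,
                    conformer_id=c,
                    pose_mode=manifest.pose_cycle[flat % len(manifest.pose_cycle)],
                    unstable=flat in manifest.unstable_jobs,
                    seed=(manifest.seed * 100003 + flat * 7919) % (2**31),
                )
            )
            flat += 1
    return jobs


def _write_tsv(frame: pd.DataFrame, path: Path, manifest_hash: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest_hash: {manifest_hash}\n")
        frame.to_csv(fh, sep="\t", float_format="%.6g", index=index)


@dataclass
class RunResult:
    outdir: Path
    scatter: pd.DataFrame
    failures: pd.DataFrame
    series: dict[str, StabilitySeries]
    merged_contacts: dict[str, ContactMap]


def run_all(
    manifest: RunManifest,
    outdir: str | Path,
    render_plots: bool = False,
) -> RunResult:
    """Run every job of the manifest and write per-complex + pooled reports."""
    conf = manifest.config
    mhash = manifest.digest()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.info(
        "run %s: contact cutoff %.1f A, occupancy cutoff %.1f A, hbond cutoff %.1f A, "
        "min lifetime %.2f, instability cutoff %d",
        mhash, conf.contact_cutoff, conf.occupancy_cutoff, conf.hbond_cutoff,
        conf.min_lifetime, conf.instability_cutoff,
    )

    criterion = HBondCriterion(conf.hbond_cutoff, conf.hbond_angle_max)
    jobs = enumerate_complexes(manifest)

    # conformer library: generated once, clustered, medoids used for complexes
    pool = make_peptide_conformers(
        manifest.peptide_sequence, n=max(manifest.n_conformers * 4, 8), seed=manifest.seed
    )
    feats = featurize(pool)
    res = cluster_conformers(
        feats, k=manifest.n_conformers,
        perplexity=min(30.0, pool.frame_count - 1), seed=manifest.seed,
    )
    reps = representatives(pool, res)
    write_structure(reps, outdir / "conformer_representatives.pdb")

    gq_models = {gq_id: build_gq(spec, seed=manifest.seed) for gq_id, spec in manifest.gq_specs.items()}

    failures: list[dict] = []
    series_by_job: dict[str, StabilitySeries] = {}
    contact_by_gq: dict[str, list[ContactMap]] = {g: [] for g in manifest.gq_specs}
    ens_by_gq: dict[str, list[Ensemble]] = {g: [] for g in manifest.gq_specs}

    for job in jobs:
        jobdir = outdir / "jobs" / job.name
        done = jobdir / "DONE"
        data_path = jobdir / "job_data.json"
        try:
            jobdir.mkdir(parents=True, exist_ok=True)
            gq = gq_models[job.gq_id]
            pep = reps.frame(job.conformer_id)
            pose = PoseSpec(mode=job.pose_mode,
                            peptide_residue_index=manifest.anchor_residue_index)
            complex_model = place_peptide(gq, pep, pose, seed=job.seed, config=conf)
            ens = make_unfolding_trajectory(
                complex_model,
                n_frames=manifest.n_frames,
                strand_displacement_per_frame=(
                    manifest.unstable_displacement if job.unstable else 0.0
                ),
                noise_sigma=manifest.noise_sigma,
                seed=job.seed,
                config=conf,
            )
            ens_by_gq[job.gq_id].append(ens)

            resumable = done.exists() and done.read_text() == mhash and data_path.exists()
            if resumable:
                cached = json.loads(data_path.read_text())
                series = StabilitySeries(
                    np.array(cached["quartet"]), np.array(cached["intermolecular"]),
                    cached["n_quartets"], cached["label"], conf.instability_cutoff,
                )
                cmap = ContactMap(
                    cached["rows"], cached["cols"], np.array(cached["counts"]),
                    cached["contact_frames"], conf.contact_cutoff, conf.min_lifetime,
                )
                series_by_job[job.name] = series
                contact_by_gq[job.gq_id].append(cmap)
                continue

            assign = detect_quartets(ens.frame(0), criterion, conf)
            series = quartet_hbond_series(ens, assign, criterion, conf)
            series_by_job[job.name] = series
            pd.DataFrame(
                {
                    "frame": np.arange(ens.frame_count),
                    "quartet_hbonds": series.per_frame_quartet_hbonds,
                    "intermolecular_hbonds": series.per_frame_intermolecular_hbonds,
                }
            ).pipe(_write_tsv, jobdir / "stability_series.tsv", mhash, index=False)

            cmap = contact_map(
                ens, conf.contact_cutoff, conf.min_lifetime, conf,
                residue_offset=conf.first_residue_number - 1,
            )
            contact_by_gq[job.gq_id].append(cmap)
            _write_tsv(cmap.to_frame(), jobdir / "contact_map.tsv", mhash)

            for mode in MODES:
                mm = interaction_matrix(ens, assign, mode, conf.contact_cutoff, conf)
                _write_tsv(mm.table, jobdir / f"modes_{mode}.tsv", mhash)
            data_path.write_text(json.dumps({
                "quartet": series.per_frame_quartet_hbonds.tolist(),
                "intermolecular": series.per_frame_intermolecular_hbonds.tolist(),
                "n_quartets": series.n_quartets,
                "label": series.label,
                "rows": cmap.row_labels,
                "cols": cmap.col_labels,
                "counts": cmap.counts.tolist(),
                "contact_frames": cmap.n_frames,
            }))
            done.write_text(mhash)
        except Exception as exc:  # job isolation: collect, continue
            log.exception("job %s failed", job.name)
            failures.append({"job": job.name, "error": f"{type(exc).__name__}: {exc}"})

    # pooled per-GQ outputs
    pooled_dir = outdir / "pooled"
    pooled_dir.mkdir(exist_ok=True)
    merged: dict[str, ContactMap] = {}
    for gq_id, maps in contact_by_gq.items():
        if not maps:
            continue
        merged[gq_id] = merge_maps(maps)
        _write_tsv(merged[gq_id].to_frame(), pooled_dir / f"contacts_{gq_id}.tsv", mhash)
        if ens_by_gq[gq_id]:
            pooled_ens = Ensemble(
                ens_by_gq[gq_id][0].topology,
                np.concatenate([e.coords for e in ens_by_gq[gq_id]], axis=0),
            )
            grid = occupancy_grid(
                pooled_ens, conf.occupancy_spacing, conf.occupancy_cutoff, config=conf
            )
            write_dx(grid, pooled_dir / f"occupancy_{gq_id}.dx")
            assign = detect_quartets(pooled_ens.frame(0), criterion, conf)
            for mode in MODES:
                mats = [
                    interaction_matrix(e, assign, mode, conf.contact_cutoff, conf).table
                    for e in ens_by_gq[gq_id]
                ]
                _write_tsv(sum(mats), pooled_dir / f"modes_{gq_id}_{mode}.tsv", mhash)

    ids = sorted(series_by_job)
    scatter = (
        stability_scatter([series_by_job[i] for i in ids], ids)
        if ids else pd.DataFrame(columns=["complex", "mean_intermolecular", "mean_quartet", "label"])
    )
    _write_tsv(scatter, pooled_dir / "stability_scatter.tsv", mhash, index=False)
    fail_table = pd.DataFrame(failures, columns=["job", "error"])
    _write_tsv(fail_table, outdir / "failures.tsv", mhash, index=False)
    manifest.config.to_yaml(outdir / "config.yaml")

    if render_plots:
        from .plots import save_heatmap, save_stability_scatter

        save_stability_scatter(scatter, pooled_dir / "stability_scatter.png",
                               conf.instability_cutoff)
        for gq_id, m in merged.items():
            save_heatmap(m.to_frame(), pooled_dir / f"contacts_{gq_id}.png", f"contacts {gq_id}")

    return RunResult(outdir, scatter, fail_table, series_by_job, merged)
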