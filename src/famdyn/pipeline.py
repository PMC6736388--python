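"""End-to-end orchestration: inputs → refined ensemble → dynamics outputs.

``run_pipeline`` executes the full workflow on a directory of PDB files
plus an aligned FASTA (and optional subfamily labels): core/ensemble
construction, refinement, GNM mode matching, signature and conservation
profiles, cumulative overlap curves, entropy/ΔRMSF coupling, per-regime
subfamily distance matrices, sequence/structure/dynamics dendrograms,
structural PCA and ANM signature-mode projections.  All artifacts are
plain text (TSV / Newick / NMD / JSON) and a resolved config is written
back verbatim, so runs are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from . import analysis, ensemble as ens, modes as md
from .enm import ModelKind

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    pdb_dir: str
    msa: str
    outdir: str
    labels: str | None = None
    chain: str | None = None
    reference: str | None = None
    model_kind: str = "GNM"
    gnm_cutoff: float = 10.0
    anm_cutoff: float = 15.0
    occupancy_threshold: float = 0.7
    rmsd_max: float = 7.0
    seqid_max: float = 0.98
    n_modes: int | None = None
    subfamily_min_size: int = 4
    linkage: str = "upgma"
    entropy_bin_width: float = 0.15
    seed: int = 0

    def validate(self):
        if not Path(self.msa).is_file():
            raise FileNotFoundError(f"MSA file not found: {self.msa}")
        if not Path(self.pdb_dir).is_dir():
            raise FileNotFoundError(f"PDB directory not found: {self.pdb_dir}")
        if self.labels is not None and not Path(self.labels).is_file():
            raise FileNotFoundError(f"labels file not found: {self.labels}")
        if not 0 < self.occupancy_threshold <= 1:
            raise ValueError("occupancy_threshold must be in (0, 1]")


def _fmt(x) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.6g}"


def write_matrix_tsv(path, labels, matrix):
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def write_profile_tsv(path, columns: dict[str, np.ndarray],
                      index_name: str = "position"):
    keys = list(columns)
    length = len(next(iter(columns.values())))
    with open(path, "w") as fh:
        fh.write(index_name + "\t" + "\t".join(keys) + "\n")
        for i in range(length):
            fh.write(str(i + 1) + "\t" +
                     "\t".join(_fmt(columns[k][i]) for k in keys) + "\n")


def _load_inputs(cfg: PipelineConfig):
    pdb_paths = sorted(Path(cfg.pdb_dir).glob("*.pdb"))
    if not pdb_paths:
        raise FileNotFoundError(f"no .pdb files in {cfg.pdb_dir}")
    structures = ens.load_structures(pdb_paths, chain_spec=cfg.chain)
    msa = ens.read_msa(cfg.msa)
    labels = ens.read_labels(cfg.labels) if cfg.labels else None
    return structures, msa, labels


def run_pipeline(cfg: PipelineConfig, log=sys.stderr) -> dict[str, Path]:
    """Run all stages and write the output bundle; returns artifact paths."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    loglines = [f"famdyn {__version__} seed={cfg.seed}",
                f"numpy {np.__version__} python {sys.version.split()[0]}"]

    def stage(name):
        loglines.append(f"stage: {name}")
        if log is not None:
            print(f"[famdyn] {name}", file=log)

    try:
        stage("load inputs")
        structures, msa, labels = _load_inputs(cfg)

        stage("build + superpose ensemble")
        fam = ens.build_ensemble(structures, msa, cfg.occupancy_threshold,
                                 labels=labels, reference=cfg.reference)
        stage("refine ensemble")
        fam = ens.refine(fam, cfg.seqid_max, cfg.rmsd_max,
                         cfg.occupancy_threshold)
        loglines.append(f"members M={fam.n_members} core N={fam.n_core} "
                        f"reference={fam.reference_id}")
        paths["ensemble_pdb"] = out / "ensemble.pdb"
        ens.write_ensemble_pdb(fam, paths["ensemble_pdb"],
                               out / "ensemble.json")

        stage("mode spectra + matching (GNM)")
        gnm = md.build_mode_ensemble(fam, ModelKind.GNM,
                                     cutoff=cfg.gnm_cutoff,
                                     n_modes=cfg.n_modes)
        regimes = gnm.regimes()

        stage("conservation + collectivity profiles")
        cons = md.conservation_profile(gnm)
        ref_ms = gnm.mode_sets[gnm.reference_index]
        k = gnm.n_modes
        paths["conservation"] = out / "mode_conservation.tsv"
        write_profile_tsv(paths["conservation"], {
            "cc_mean": cons.cc_mean, "cc_sd": cons.cc_sd,
            "collectivity_ref": ref_ms.collectivity[:k],
            "weight_ref": ref_ms.weights[:k],
        }, index_name="mode")

        stage("cumulative overlap curve")
        curve = md.cumulative_overlap_curve(gnm)
        paths["overlap_curve"] = out / "cumulative_overlap.tsv"
        write_profile_tsv(paths["overlap_curve"], {
            "so_mean": curve.so_mean, "so_sd": curve.so_sd,
            "cum_weight": curve.cum_weight,
        }, index_name="n_modes")
        loglines.append(f"overlap minimum at n={curve.argmin}")

        stage("signature MSF + covariance")
        for name, win in (("global", regimes.get("global")),
                          ("lf", regimes.get("lf"))):
            if win is None:
                continue
            prof = md.signature_msf(gnm, win)
            p = out / f"signature_msf_{name}.tsv"
            write_profile_tsv(p, {"mean": prof.mean, "sd": prof.sd,
                                  "min": prof.min, "max": prof.max})
            paths[f"signature_msf_{name}"] = p
        covwin = (1, min(20, k))
        cov = md.signature_covariance(gnm, covwin)
        paths["covariance_mean"] = out / "covariance_mean.tsv"
        paths["covariance_sd"] = out / "covariance_sd.tsv"
        ids = [str(c + 1) for c in range(fam.n_core)]
        write_matrix_tsv(paths["covariance_mean"], ids, cov.mean)
        write_matrix_tsv(paths["covariance_sd"], ids, cov.sd)

        stage("entropy / ΔRMSF coupling")
        h = analysis.shannon_entropy(fam)
        drmsf = {name: analysis.delta_rmsf(gnm, win)
                 for name, win in regimes.items()}
        paths["divergence"] = out / "entropy_drmsf.tsv"
        write_profile_tsv(paths["divergence"], {"entropy": h, **{
            f"drmsf_{name}": v for name, v in drmsf.items()}})
        try:
            curve_ed = analysis.entropy_binned_divergence(
                h, drmsf.get("ltif", next(iter(drmsf.values()))),
                bin_width=cfg.entropy_bin_width)
            loglines.append(
                f"entropy lognormal fit mu={curve_ed.lognorm_mu:.4f} "
                f"sigma={curve_ed.lognorm_sigma:.4f} r={curve_ed.pearson_r:.4f}")
            paths["entropy_curve"] = out / "entropy_binned_drmsf.tsv"
            with open(paths["entropy_curve"], "w") as fh:
                fh.write("bin_center\tmean_drmsf\tn_columns\n")
                for c, v, n in zip(curve_ed.bin_centers,
                                   curve_ed.mean_divergence,
                                   curve_ed.bin_counts):
                    fh.write(f"{c:.6g}\t{v:.6g}\t{n}\n")
        except ValueError as exc:
            loglines.append(f"entropy fit skipped: {exc}")

        stage("distance matrices + dendrograms")
        # the dynamics tree uses the regime that discriminates subfamilies
        dyn_win = regimes.get("ltif", regimes.get("global"))
        dms = {"sequence": analysis.sequence_distance_matrix(fam),
               "structure": analysis.rmsd_distance_matrix(fam),
               "dynamics": analysis.spectral_distance_matrix(gnm, dyn_win)}
        for name, dm in dms.items():
            p = out / f"distance_{name}.tsv"
            write_matrix_tsv(p, dm.labels, dm.matrix)
            paths[f"distance_{name}"] = p
            newick, order, _ = analysis.dendrogram(dm, cfg.linkage)
            pt = out / f"tree_{name}.nwk"
            pt.write_text(newick + "\n")
            paths[f"tree_{name}"] = pt
            loglines.append(f"{name} leaf order: {' '.join(order)}")

        if fam.subfamily_labels is not None:
            stage("subfamily spectral distances per regime")
            for name, win in regimes.items():
                try:
                    sub = analysis.subfamily_distances(
                        gnm, fam.subfamily_labels, win,
                        min_size=cfg.subfamily_min_size)
                except ValueError as exc:
                    loglines.append(f"subfamily matrix ({name}) skipped: {exc}")
                    break
                p = out / f"subfamily_distance_{name}.tsv"
                write_matrix_tsv(p, sub.labels, sub.matrix)
                paths[f"subfamily_{name}"] = p

        stage("ANM signature modes + projections")
        try:
            anm = md.build_mode_ensemble(fam, ModelKind.ANM,
                                         cutoff=cfg.anm_cutoff,
                                         n_modes=max(20, cfg.n_modes or 0))
            proj = analysis.project_on_signature_modes(anm, fam)
            pca = analysis.structure_pca(fam)
            paths["projections"] = out / "projections.tsv"
            with open(paths["projections"], "w") as fh:
                fh.write("member\tsig_mode1\tsig_mode2\tpc1\tpc2\n")
                pca_map = dict(zip(pca.member_ids, pca.projections))
                for i, mid in enumerate(fam.member_ids):
                    pc = pca_map.get(mid, [float("nan")] * 2)
                    fh.write(f"{mid}\t{proj[i, 0]:.6g}\t{proj[i, 1]:.6g}"
                             f"\t{pc[0]:.6g}\t{pc[1]:.6g}\n")
            sig = np.column_stack([
                anm.vectors[:, :, k].mean(axis=0) for k in range(2)])
            sig /= np.linalg.norm(sig, axis=0)
            paths["signature_nmd"] = out / "signature_modes.nmd"
            md.write_nmd(paths["signature_nmd"], "signature",
                         fam.mean_coords(), sig)
        except ValueError as exc:
            loglines.append(f"ANM stage skipped: {exc}")
    except Exception as exc:
        loglines.append(f"ERROR: {exc}")
        (out / "run.log").write_text("\n".join(loglines) + "\n")
        raise

    paths["config"] = out / "config.json"
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, sort_keys=True) + "\n")
    paths["log"] = out / "run.log"
    paths["log"].write_text("\n".join(loglines) + "\n")
    return paths
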