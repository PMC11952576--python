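"""End-to-end orchestration: simulate -> preprocess -> GLM -> images -> stats.

`run_pipeline` executes the full paired-array comparison on a synthetic
cohort and writes a report directory of CSV tables and a JSON summary; all
randomness derives from one master seed and reruns with an identical
configuration reproduce identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .forward import compute_sensitivity
from .glm import build_design, fit_glm
from .headmodel import HeadMeshConfig, build_head_mesh
from .optics import DEFAULT_WAVELENGTHS_NM, OpticalProperties
from .preprocess import exclude_subject, preprocess_recording
from .probes import HDProbeConfig, SparseProbeConfig, build_hd_probe, \
    build_sparse_probe
from .recon import ReconConfig, build_regularized_system, hrf_to_od, \
    reconstruct, unmix_vertices
from .simulate import CohortSpec, GroundTruth, generate_group
from .stats import block_delta, critical_t, group_tstat, paired_compare, \
    paired_condition_contrast, roi_channels_from_labels, \
    roi_vertices_from_sensitivity, select_roi_extreme, select_top_vertices, \
    tstat

CONDITIONS = ("congruent", "incongruent")
CHROMOPHORES = ("HbO", "HbR")
SIDES = ("left", "right")


@dataclass
class PipelineConfig:
    seed: int = 7
    cohort: CohortSpec = field(default_factory=CohortSpec)
    truth: GroundTruth = field(default_factory=GroundTruth)
    mesh: HeadMeshConfig = field(default_factory=HeadMeshConfig)
    sparse_probe: SparseProbeConfig = field(default_factory=SparseProbeConfig)
    hd_probe: HDProbeConfig = field(default_factory=HDProbeConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    wavelengths_nm: tuple = DEFAULT_WAVELENGTHS_NM
    ppf: float = 1.0
    top_k_vertices: int = 25
    alpha: float = 0.05
    motion_correction: bool = True
    make_figures: bool = False
    out_dir: str | None = None


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str
    n_subjects: int
    artifacts: dict = field(default_factory=dict)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_arrays(config: PipelineConfig):
    """Probes, mesh and per-wavelength sensitivity matrices for both arrays."""
    mesh = build_head_mesh(config.mesh)
    probes = {"sparse": build_sparse_probe(config.sparse_probe),
              "hd": build_hd_probe(config.hd_probe)}
    props = OpticalProperties()
    sens = {
        name: tuple(compute_sensitivity(probe, mesh, props, wl, ppf=config.ppf)
                    for wl in config.wavelengths_nm)
        for name, probe in probes.items()
    }
    return probes, mesh, sens


def process_recording(rec, config: PipelineConfig):
    """Preprocess one recording and fit its GLM; None when excluded."""
    conc = preprocess_recording(rec, motion_correction=config.motion_correction)
    if exclude_subject(conc):
        return None
    design = build_design(rec.events, conc.sample_rate_hz, conc.conc.shape[0])
    hrf = fit_glm(conc, design)
    conc_clean = conc
    if hrf.clean_conc is not None:
        import dataclasses

        conc_clean = dataclasses.replace(
            conc,
            conc=np.concatenate(
                [hrf.clean_conc, hrf.clean_conc.sum(axis=2, keepdims=True)],
                axis=2))
        conc_clean.rejected_blocks = conc.rejected_blocks
    return {"conc": conc, "conc_clean": conc_clean, "hrf": hrf,
            "prune": conc.prune_stats}


def _image_block_stats(deltas_conc, rows, systems, probe, ppf, wavelengths):
    """Per-block vertex images from channel block deltas, then vertex t."""
    # deltas_conc: (n_blocks, n_channels, 2) over full channel list
    od = hrf_to_od(deltas_conc, probe, channel_rows=rows, ppf=ppf,
                   wavelengths=wavelengths)          # (n_blocks, n_rows, 2)
    images = [reconstruct(od[:, :, w].T, systems[w]).T
              for w in range(len(wavelengths))]
    stack = unmix_vertices(images, wavelengths)      # (n_blocks, n_vertices, 2)
    return stack, tstat(stack[:, :, 0]), tstat(stack[:, :, 1])


def run_pipeline(config: PipelineConfig | None = None,
                 keep_hrfs: bool = False):
    """Run the full sparse-vs-HD comparison on a synthetic cohort.

    Returns a results dictionary; when ``config.out_dir`` is set, CSV
    tables, a JSON summary and (optionally) figures are written there.
    ``keep_hrfs`` retains every recording's HRF estimate in the results
    (for downstream parameter-recovery analyses).
    """
    config = config or PipelineConfig()
    probes, mesh, sens = build_arrays(config)
    recordings = generate_group(sens, mesh, config.truth, config.cohort,
                                seed=config.seed)

    roi_channels = {name: roi_channels_from_labels(probe, mesh)
                    for name, probe in probes.items()}
    roi_vertex_sets = {
        side: roi_vertices_from_sensitivity(sens["hd"][0],
                                            roi_channels["hd"][side])
        for side in SIDES
    }

    processed = {}
    excluded = []
    for rec in recordings:
        out = process_recording(rec, config)
        if out is None:
            excluded.append((rec.subject_id, rec.array_id))
            continue
        processed[(rec.subject_id, rec.array_id)] = out
    # pairwise exclusion: a subject must survive with both arrays
    subjects = sorted({s for s, _ in processed}
                      & {s for s, a in processed if a == "sparse"}
                      & {s for s, a in processed if a == "hd"})
    subjects = [s for s in subjects
                if (s, "sparse") in processed and (s, "hd") in processed]

    # ---- channel-space block statistics --------------------------------
    channel_rows = []
    selected = {}      # (array, side, cond, chrom) -> {subject: value}
    subject_block_means = {}  # (array, cond, chrom) -> {subject: (n_ch,) means}
    for (subj, array), out in processed.items():
        if subj not in subjects:
            continue
        for cond in CONDITIONS:
            for chrom in CHROMOPHORES:
                bs = block_delta(out["conc_clean"], cond, chrom)
                means = np.where(out["conc"].channel_mask,
                                 bs.deltas.mean(axis=0), np.nan)
                subject_block_means.setdefault((array, cond, chrom), {})[subj] \
                    = means
                for side in SIDES:
                    ch, val = select_roi_extreme(
                        bs.t, roi_channels[array][side], chrom)
                    selected.setdefault((array, side, cond, chrom), {})[subj] \
                        = val
                    channel_rows.append({
                        "subject": subj, "array": array, "side": side,
                        "condition": cond, "chromophore": chrom,
                        "channel": ch, "t": val, "n_blocks": bs.n_blocks})

    comparisons = {}
    contrasts = {}
    for side in SIDES:
        for cond in CONDITIONS:
            for chrom in CHROMOPHORES:
                key = (side, cond, chrom)
                comparisons[("channel",) + key] = paired_compare(
                    selected[("sparse", side, cond, chrom)],
                    selected[("hd", side, cond, chrom)])
        for array in probes:
            for chrom in CHROMOPHORES:
                t, p, n = paired_condition_contrast(
                    selected[(array, side, "incongruent", chrom)],
                    selected[(array, side, "congruent", chrom)])
                contrasts[("channel", array, side, chrom)] = \
                    {"t": t, "p": p, "n": n}

    # ---- group channel maps with critical-t masking --------------------
    t_crit = critical_t(len(subjects), config.alpha)
    group_maps = {}
    for (array, cond, chrom), per_subj in subject_block_means.items():
        mat = np.vstack([per_subj[s] for s in subjects])
        t, n = group_tstat(mat)
        masked = np.where(np.abs(t) >= t_crit, t, np.nan)
        group_maps[(array, cond, chrom)] = {"t": t, "masked": masked, "n": n}

    # ---- image-space statistics ----------------------------------------
    image_rows = []
    selected_img = {}
    recon_systems = {}
    for (subj, array), out in processed.items():
        if subj not in subjects:
            continue
        probe = probes[array]
        rows = np.array([c for c in np.flatnonzero(out["conc"].channel_mask)
                         if probe.channels[c][2] != "short"], dtype=int)
        key = (array, tuple(rows.tolist()))
        if key not in recon_systems:
            recon_systems[key] = tuple(
                build_regularized_system(sens[array][w], config.recon,
                                         channel_rows=rows)
                for w in range(len(config.wavelengths_nm)))
        systems = recon_systems[key]
        for cond in CONDITIONS:
            bs = block_delta(out["conc_clean"], cond, "HbO")
            bs_r = block_delta(out["conc_clean"], cond, "HbR")
            deltas = np.stack([bs.deltas, bs_r.deltas], axis=2)
            _stack, t_hbo, t_hbr = _image_block_stats(
                deltas, rows, systems, probe, config.ppf,
                config.wavelengths_nm)
            for chrom, tvals in (("HbO", t_hbo), ("HbR", t_hbr)):
                for side in SIDES:
                    val = select_top_vertices(tvals, roi_vertex_sets[side],
                                              config.top_k_vertices, chrom)
                    selected_img.setdefault((array, side, cond, chrom), {})[subj] \
                        = val
                    image_rows.append({
                        "subject": subj, "array": array, "side": side,
                        "condition": cond, "chromophore": chrom, "t": val})

    for side in SIDES:
        for cond in CONDITIONS:
            for chrom in CHROMOPHORES:
                key = (side, cond, chrom)
                comparisons[("image",) + key] = paired_compare(
                    selected_img[("sparse", side, cond, chrom)],
                    selected_img[("hd", side, cond, chrom)])
        for array in probes:
            for chrom in CHROMOPHORES:
                t, p, n = paired_condition_contrast(
                    selected_img[(array, side, "incongruent", chrom)],
                    selected_img[(array, side, "congruent", chrom)])
                contrasts[("image", array, side, chrom)] = \
                    {"t": t, "p": p, "n": n}

    results = {
        "subjects": subjects,
        "excluded": excluded,
        "t_crit": t_crit,
        "comparisons": comparisons,
        "contrasts": contrasts,
        "group_maps": group_maps,
        "channel_table": pd.DataFrame(channel_rows),
        "image_table": pd.DataFrame(image_rows),
        "roi_channels": roi_channels,
        "roi_vertex_sets": roi_vertex_sets,
        "probes": probes,
        "mesh": mesh,
        "sensitivities": sens,
        "config": config,
    }
    if keep_hrfs:
        results["hrfs"] = {key: out["hrf"] for key, out in processed.items()}
        results["ground_truths"] = {r.subject_id: r.ground_truth
                                    for r in recordings if r.array_id == "hd"}

    if config.out_dir is not None:
        _write_report(results, config)
    return results


def _comparison_frame(comparisons: dict) -> pd.DataFrame:
    rows = []
    for (space, side, cond, chrom), c in comparisons.items():
        rows.append({
            "space": space, "side": side, "condition": cond,
            "chromophore": chrom, "n": len(c.subject_ids),
            "mean_sparse": c.mean_sparse, "se_sparse": c.se_sparse,
            "mean_hd": c.mean_hd, "se_hd": c.se_hd,
            "t": c.t, "p": c.p})
    return pd.DataFrame(rows)


def _write_report(results: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed,
                           software_version=__version__,
                           n_subjects=len(results["subjects"]))

    results["channel_table"].to_csv(out / "channel_selected.csv", index=False)
    results["image_table"].to_csv(out / "image_selected.csv", index=False)
    comp = _comparison_frame(results["comparisons"])
    comp.to_csv(out / "array_comparisons.csv", index=False)

    summary = {
        "subjects": results["subjects"],
        "excluded": results["excluded"],
        "t_crit": results["t_crit"],
        "array_comparisons": comp.to_dict(orient="records"),
        "condition_contrasts": {
            "/".join(k): v for k, v in results["contrasts"].items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest.artifacts = {p.name: manifest.config_hash
                          for p in out.glob("*.csv")}
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))

    if config.make_figures:
        _figures(results, out)


def _figures(results: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comp = _comparison_frame(results["comparisons"])
    for space in ("channel", "image"):
        sub = comp[(comp.space == space) & (comp.chromophore == "HbO")]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(sub))
        ax.bar(x - 0.2, sub.mean_sparse, 0.4, yerr=sub.se_sparse,
               label="sparse", color="tab:gray")
        ax.bar(x + 0.2, sub.mean_hd, 0.4, yerr=sub.se_hd,
               label="HD", color="tab:red")
        ax.axhline(results["t_crit"], ls="--", c="k", lw=0.8,
                   label="critical t")
        ax.set_xticks(x)
        ax.set_xticklabels([f"{r.side}\n{r.condition}"
                            for r in sub.itertuples()], fontsize=8)
        ax.set_ylabel("ROI-extreme HbO t-statistic")
        ax.set_title(f"{space} space")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"roi_bars_{space}.png", dpi=120)
        plt.close(fig)
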