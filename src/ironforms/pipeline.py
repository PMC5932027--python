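"""End-to-end orchestration: simulate -> fit per modality -> assemble -> stats.

Each stage communicates with the next only through its declared files
(NIfTI stacks, two-column CSV signal tables with JSON sidecars, cohort
CSVs), so stages can equally be run as separate processes through the CLI.
A run is fully determined by its configuration and seed; the manifest
records every stage output and every seed consumed, and reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import epr as epr_mod
from . import io as fio
from . import magnetometry as mag
from . import relaxometry as rlx
from . import stats as cst
from . import synthetic as syn

__all__ = ["RunConfig", "run_pipeline", "assemble_panel"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs, with defaults for every knob."""

    seed: int = 0
    n_ad: int = 22
    n_control: int = 14
    # modality noise levels
    mri_noise_sd: float = 0.05       # Rician channel sd, fraction of prefactor
    squid_noise_frac: float = 0.01   # Gaussian sd, fraction of Ms*f
    epr_noise_frac: float = 0.01     # Gaussian sd, fraction of template peak
    # fit options
    alpha: float = 0.5               # Neel exponent
    ms_magnetite: float = 84.0
    ms_ferrihydrite: float = 0.62
    snr_threshold: float = 4.0
    noise_floor_emu: float = 1.0e-8
    ttest: str = "student"           # student | welch
    r2star_method: str = "log-linear"
    # synthesis details
    grid_shape: tuple = (24, 24)
    epr_orientations: int = 400
    irm_b_offset: float = 0.0
    marginal_sampling: str = "stratified"
    outdir: str = "ironforms_run"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def _cohort_spec(cfg: RunConfig) -> syn.CohortSpec:
    spec = syn.default_cohort_spec(n_ad=cfg.n_ad, n_control=cfg.n_control,
                                   seed=cfg.seed, alpha=cfg.alpha)
    return dataclasses.replace(spec, marginal_sampling=cfg.marginal_sampling)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path, log: list) -> dict:
    """Generate the ground-truth cohort and the raw per-subject signals."""
    raw = outdir / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    spec = _cohort_spec(cfg)
    panels = syn.generate_cohort(spec)
    truth = syn.cohort_to_frame(panels)
    fio.save_cohort(outdir / "cohort_truth.csv", truth)

    template = epr_mod.simulate_spectrum(orientations=cfg.epr_orientations)
    fio.save_spectrum(outdir / "epr_template.csv", template)
    ref = syn.reference_from_template(template)
    (outdir / "epr_reference.json").write_text(json.dumps({
        "identity": ref.identity, "concentration": ref.concentration,
        "integral": ref.integral, "mass_g": ref.mass_g,
        "temperature_k": ref.temperature_k}, indent=1))

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(panels))
    roi = syn.central_roi(cfg.grid_shape)
    fio.save_mask(raw / "roi.nii", roi)
    for panel, child in zip(panels, children):
        log.append(f"simulate subject={panel.subject} "
                   f"seed_entropy={child.entropy}/{child.spawn_key}")
        rng = np.random.default_rng(child)
        stack = syn.synthesize_echo_stack(
            panel, noise_sd=cfg.mri_noise_sd, shape=cfg.grid_shape, rng=rng)
        fio.save_echo_stack(raw / f"echo_{panel.subject}.nii", stack)
        for temp, ms_key in ((100.0, "magnetite"), (5.0, "ferrihydrite")):
            ms = cfg.ms_magnetite if temp == 100.0 else cfg.ms_ferrihydrite
            f_true = (panel.magnetite * 1e-9 if temp == 100.0
                      else panel.ferrihydrite * 1e-6)
            curve = syn.synthesize_irm(
                panel, temp, noise_sd=cfg.squid_noise_frac * ms * f_true,
                b_offset=cfg.irm_b_offset, alpha=cfg.alpha,
                noise_floor_emu=cfg.noise_floor_emu, rng=rng)
            fio.save_irm(raw / f"irm{int(temp)}_{panel.subject}.csv", curve)
        spectrum = syn.synthesize_epr_spectrum(
            panel, template, ref, noise_sd=cfg.epr_noise_frac, rng=rng)
        fio.save_spectrum(raw / f"epr_{panel.subject}.csv", spectrum)
    return {"subjects": [p.subject for p in panels],
            "files": ["cohort_truth.csv", "epr_template.csv",
                      "epr_reference.json", "raw/"]}


def stage_r2star(cfg: RunConfig, outdir: Path, log: list) -> dict:
    subjects = fio.load_cohort(outdir / "cohort_truth.csv")["subject"]
    roi = fio.load_mask(outdir / "raw" / "roi.nii")
    rows = []
    for sid in subjects:
        stack = fio.load_echo_stack(outdir / "raw" / f"echo_{sid}.nii")
        r2map = rlx.fit_r2star(stack, method=cfg.r2star_method)
        summ = rlx.roi_median(r2map, roi)
        rows.append({"subject": sid, "r2star": summ.median_r2star,
                     "roi_voxels": summ.voxel_count})
    out = pd.DataFrame(rows)
    fio.save_cohort(outdir / "fit_r2star.csv", out)
    log.append(f"r2star: fitted {len(rows)} subjects")
    return {"files": ["fit_r2star.csv"]}


def stage_epr(cfg: RunConfig, outdir: Path, log: list) -> dict:
    subjects = fio.load_cohort(outdir / "cohort_truth.csv")["subject"]
    template = fio.load_spectrum(outdir / "epr_template.csv")
    tdi = epr_mod.double_integral(template)
    refd = json.loads((outdir / "epr_reference.json").read_text())
    ref = epr_mod.ReferenceSample(concentration=refd["concentration"],
                                  integral=refd["integral"],
                                  mass_g=refd["mass_g"],
                                  temperature_k=refd["temperature_k"])
    rows = []
    for sid in subjects:
        spectrum = fio.load_spectrum(outdir / "raw" / f"epr_{sid}.csv")
        fit = epr_mod.fit_amplitude(spectrum, template)
        fe3 = epr_mod.quantify_fe3(fit.scale, tdi, ref,
                                   spectrum.sample_mass_g)
        rows.append({"subject": sid, "fe3": fe3, "epr_scale": fit.scale})
    fio.save_cohort(outdir / "fit_epr.csv", pd.DataFrame(rows))
    log.append(f"epr: quantified {len(rows)} subjects")
    return {"files": ["fit_epr.csv"]}


def stage_irm(cfg: RunConfig, outdir: Path, log: list) -> dict:
    subjects = fio.load_cohort(outdir / "cohort_truth.csv")["subject"]
    rows = []
    for sid in subjects:
        c100 = fio.load_irm(outdir / "raw" / f"irm100_{sid}.csv")
        c5 = fio.load_irm(outdir / "raw" / f"irm5_{sid}.csv")
        res = mag.analyze_subject(c100, c5, alpha=cfg.alpha,
                                  ms_magnetite=cfg.ms_magnetite,
                                  ms_ferrihydrite=cfg.ms_ferrihydrite,
                                  snr_threshold=cfg.snr_threshold)
        rows.append({"subject": sid,
                     "magnetite": res.magnetite_ng_per_g,
                     "magnetite_moment": res.magnetite_moment_bohr,
                     "ferrihydrite": res.ferrihydrite_ug_per_g,
                     "lf": res.loading_factor,
                     "flr": res.loading_ratio_pct,
                     "irm100_usable": res.fits["100K"].usable})
    fio.save_cohort(outdir / "fit_irm.csv", pd.DataFrame(rows))
    log.append(f"irm: fitted {len(rows)} subjects")
    return {"files": ["fit_irm.csv"]}


def assemble_panel(outdir: Path) -> pd.DataFrame:
    """Merge the per-modality fit tables with the cohort covariates."""
    truth = fio.load_cohort(outdir / "cohort_truth.csv")
    cov = truth[["subject", "group", "braak", "age", "sex"]]
    merged = cov
    for name in ("fit_r2star.csv", "fit_epr.csv", "fit_irm.csv"):
        merged = merged.merge(fio.load_cohort(outdir / name), on="subject")
    return merged


def stage_assemble(cfg: RunConfig, outdir: Path, log: list) -> dict:
    panel = assemble_panel(outdir)
    fio.save_cohort(outdir / "cohort_measured.csv", panel)
    log.append(f"assemble: {len(panel)} subjects merged")
    return {"files": ["cohort_measured.csv"]}


def stage_stats(cfg: RunConfig, outdir: Path, log: list) -> dict:
    table = fio.load_cohort(outdir / "cohort_measured.csv")
    tests = cst.group_tests(table)
    fio.save_cohort(outdir / "stats_tests.csv", tests)

    report: dict = {"groups": {}}
    rhos = {}
    for grp in ("AD", "control"):
        rho, p = cst.correlogram(table, group=grp)
        rho.to_csv(outdir / f"correlogram_{grp}.csv")
        p.to_csv(outdir / f"correlogram_{grp}_p.csv")
        rhos[grp] = rho
        report["groups"][grp] = {"n": int((table["group"] == grp).sum())}

    comparisons = []
    rho_ad, rho_c = rhos["AD"], rhos["control"]
    n_ad = int((table["group"] == "AD").sum())
    n_c = int((table["group"] == "control").sum())
    for a, b in (("fe3", "ferrihydrite"), ("ferrihydrite", "flr"),
                 ("fe3", "flr")):
        r1, r2 = rho_ad.loc[a, b], rho_c.loc[a, b]
        if not (abs(r1) < 1 and abs(r2) < 1):
            # Fisher z is infinite at |rho| = 1 (possible at very small n)
            comparisons.append({"pair": [a, b], "rho_ad": float(r1),
                                "rho_control": float(r2), "z_diff": None,
                                "p": None, "skipped": "degenerate rho"})
            continue
        cc = cst.compare_correlations(r1, n_ad, r2, n_c, pair=(a, b))
        comparisons.append({"pair": [a, b], "rho_ad": cc.rho1,
                            "rho_control": cc.rho2, "z_diff": cc.z_diff,
                            "p": cc.p})
    report["correlation_comparisons"] = comparisons

    partials = {}
    for xx, yy, zz in (("fe3", "flr", "ferrihydrite"),
                       ("ferrihydrite", "flr", "fe3"),
                       ("fe3", "ferrihydrite", "flr")):
        r, p = cst.partial_correlation(table, xx, yy, zz)
        partials[f"{xx}~{yy}|{zz}"] = {"r": r, "p": p}
    report["partial_correlations"] = partials

    strata = cst.braak_stratify(table)
    fio.save_cohort(outdir / "braak_strata.csv", strata)
    (outdir / "stats_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    log.append("stats: report written")
    return {"files": ["stats_tests.csv", "correlogram_AD.csv",
                      "correlogram_control.csv", "braak_strata.csv",
                      "stats_report.json"]}


STAGES = (("simulate", stage_simulate), ("r2star", stage_r2star),
          ("epr", stage_epr), ("irm", stage_irm),
          ("assemble", stage_assemble), ("stats", stage_stats))


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all six stages under ``cfg.outdir``; returns the manifest path.

    Any stage failure aborts with an error naming the stage.  The manifest
    lists the seed, the package version and every stage's outputs; a rerun
    with the same config produces byte-identical files.
    """
    from . import __version__

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={cfg.seed}"]
    manifest = {"seed": cfg.seed, "version": __version__, "stages": {}}
    cfg.to_yaml(outdir / "config.yaml")
    for name, fn in STAGES:
        try:
            manifest["stages"][name] = fn(cfg, outdir, log)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def report_hash(outdir: str | Path) -> str:
    """SHA-256 over the pipeline's declared outputs (determinism checks)."""
    outdir = Path(outdir)
    h = hashlib.sha256()
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name not in ("run.log", "config.yaml"):
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
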