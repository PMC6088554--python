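"""Full synthetic study: ensembles -> observables -> instrument closure.

For every requested (alloform, charge state) combination the pipeline samples
a conformational ensemble with the replica-exchange model, computes ensemble
CCS (EHSS) and Förster FRET efficiency, summarises the hydrophobic-core
Ramachandran occupancies, forward-generates synthetic instrument data from
the computed observables and reduces them back (closure), and emits a CCS vs
FRET table and figures.  Everything is reproducible from one master seed,
which is fanned out to per-stage seeds by hashing the stage name.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conformer_model as cm
from .action_fret import action_fret_efficiency, fragmentation_yield
from .ccs import CCSSettings, CollisionRadiiTable, ensemble_ccs
from .fret import default_chromophore_spec, ensemble_fret
from .ims import fit_mobility
from .instrument import InstrumentTruth, synth_atd_series, synth_spectra
from .rama import (
    CORE_RESIDUES,
    family_summary,
    load_reference_set,
    rama_plot,
)
from .structure_io import compute_dihedrals, write_pdb

__all__ = ["StudyConfig", "StudyResult", "run_study", "stage_seed"]

log = logging.getLogger("abfret")

SCHEMA_VERSION = 1


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: stage name hashed with the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class StudyConfig:
    """Everything needed to run the synthetic study; validates up front."""

    alloforms: tuple = ("WT", "F19P")
    charge_states: tuple = (3, 4, 5, 6)
    master_seed: int = 1
    output_dir: str = "abfret_study"
    # sampler
    ladder_t_min: float = 220.0
    ladder_t_max: float = 850.0
    ladder_n: int = 20
    n_steps: int = 24000
    stride: int = 100
    burn_in: int = 4000
    exchange_interval: int = 200
    sample_rung: int = 4  # the 292 K rung of the default ladder
    donor_terminus: str = "C"
    energy_params: cm.ToyEnergyParams = field(default_factory=cm.ToyEnergyParams)
    # CCS (scaled-down Monte Carlo for per-conformer batches)
    ccs_method: str = "ehss"
    ccs_orientations: int = 32
    ccs_trajectories: int = 150
    # FRET
    r0_iso: float = 49.0
    kappa2_mode: str = "explicit"
    # synthetic instrument closure
    instrument_counts: int = 10**6
    instrument_repeats: int = 5
    instrument_voltages: tuple = (300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0)
    instrument_noise_frac: float = 0.02
    ion_mass: float = 3400.0  # Da, grafted construct fixture value
    write_ensembles: bool = False
    make_plots: bool = True

    def validate(self) -> None:
        if not self.alloforms or not self.charge_states:
            raise ValueError("alloforms and charge_states must be non-empty")
        for a in self.alloforms:
            if a not in ("WT", "F19P"):
                raise ValueError(f"unknown alloform {a!r}")
        for z in self.charge_states:
            if z not in (3, 4, 5, 6):
                raise ValueError("charge states must be within 3..6")
        if not 0 <= self.sample_rung < self.ladder_n:
            raise ValueError("sample_rung outside the ladder")
        if self.n_steps < self.stride:
            raise ValueError("n_steps must be at least stride")
        CCSSettings(
            method=self.ccs_method,
            n_orientations=self.ccs_orientations,
            n_trajectories=self.ccs_trajectories,
        )

    # -- plain-text round trip ------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["energy_params"] = _params_to_dict(self.energy_params)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "master_seed" not in data:
            raise ValueError("config must declare master_seed explicitly")
        params = data.pop("energy_params", None)
        for key in ("alloforms", "charge_states", "instrument_voltages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        cfg = cls(**data)
        if params is not None:
            cfg.energy_params = _params_from_dict(params)
        return cfg


def _params_to_dict(p: cm.ToyEnergyParams) -> dict:
    d = asdict(p)
    d["basins"] = {
        name: {"phi": b["phi"], "psi": b["psi"], "depth": b["depth"], "width": b["width"]}
        for name, b in p_basins_items(p)
    }
    d["proline_phi_range"] = list(p.proline_phi_range)
    return d


def p_basins_items(p: cm.ToyEnergyParams):
    for name, b in p.basins:
        yield name, {"phi": b.phi, "psi": b.psi, "depth": b.depth, "width": b.width}


def _params_from_dict(d: dict) -> cm.ToyEnergyParams:
    d = dict(d)
    basins = tuple(
        (name, cm.TorsionBasin(b["phi"], b["psi"], b["depth"], b["width"]))
        for name, b in d.pop("basins").items()
    )
    d["proline_phi_range"] = tuple(d["proline_phi_range"])
    return cm.ToyEnergyParams(basins=basins, **d)


@dataclass
class StudyResult:
    """Per-combination observables plus failure records."""

    table: pd.DataFrame
    failures: list
    output_dir: Path

    @property
    def ok(self) -> bool:
        return not self.failures


def _core_dihedral_points(ensemble):
    pts = []
    for conf in ensemble.conformers:
        for rec in compute_dihedrals(conf, CORE_RESIDUES):
            pts.append((rec.phi, rec.psi))
    return np.array(pts)


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the full study; partial failure of one combination is recorded and
    the remaining combinations still complete."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    ladder = cm.temperature_ladder(cfg.ladder_t_min, cfg.ladder_t_max, cfg.ladder_n)
    radii = CollisionRadiiTable()
    ccs_settings = CCSSettings(
        method=cfg.ccs_method,
        n_orientations=cfg.ccs_orientations,
        n_trajectories=cfg.ccs_trajectories,
    )
    rows = []
    failures = []
    refs = [load_reference_set("solution_monomer"), load_reference_set("fibril")]
    for alloform in cfg.alloforms:
        seq = (cm.wild_type if alloform == "WT" else cm.f19p)(cfg.donor_terminus)
        chromo = default_chromophore_spec(seq, cfg.r0_iso)
        for z in cfg.charge_states:
            tag = f"{alloform}_{z}plus"
            t_start = time.time()
            try:
                state = cm.assign_protons(seq, z - 2, cfg.energy_params)
                ens = cm.sample_ensemble(
                    seq,
                    state,
                    cfg.energy_params,
                    ladder,
                    n_steps=cfg.n_steps,
                    stride=cfg.stride,
                    seed=stage_seed(cfg.master_seed, f"sample:{tag}"),
                    exchange_interval=cfg.exchange_interval,
                    burn_in=cfg.burn_in,
                    sample_rung=cfg.sample_rung,
                )
                if cfg.write_ensembles:
                    write_pdb(ens.conformers, outdir / f"ensemble_{tag}.pdb")
                ccs_results, (ccs_mean, ccs_sd) = ensemble_ccs(
                    ens,
                    radii,
                    replace(
                        ccs_settings, seed=stage_seed(cfg.master_seed, f"ccs:{tag}")
                    ),
                )
                ccs_se = ccs_sd / np.sqrt(len(ccs_results)) if len(ccs_results) > 1 else 0.0
                fret = ensemble_fret(ens, chromo, kappa2_mode=cfg.kappa2_mode)
                occ, n_missing = family_summary(ens)
                # instrument closure on the computed observables
                eff_truth = float(np.clip(fret.ensemble_mean_efficiency, 0.0, 1.0))
                truth = InstrumentTruth(
                    true_efficiency=eff_truth,
                    true_ccs=ccs_mean,
                    charge=z,
                    ion_mass=cfg.ion_mass,
                    counts_budget=cfg.instrument_counts,
                    seed=stage_seed(cfg.master_seed, f"instrument:{tag}"),
                )
                s505, s545 = synth_spectra(truth, cfg.instrument_repeats)
                eff_rec = action_fret_efficiency(
                    [fragmentation_yield(s) for s in s505],
                    [fragmentation_yield(s) for s in s545],
                )
                mob = fit_mobility(
                    synth_atd_series(
                        truth, cfg.instrument_voltages, cfg.instrument_noise_frac
                    )
                )
                rows.append(
                    {
                        "alloform": alloform,
                        "charge": z,
                        "n_structures": len(ens),
                        "ccs_mean_A2": ccs_mean,
                        "ccs_sd_A2": ccs_sd,
                        "ccs_se_A2": ccs_se,
                        "fret_mean": fret.ensemble_mean_efficiency,
                        "fret_sd": float(fret.efficiency.std(ddof=1)),
                        "mean_R_A": float(fret.r.mean()),
                        "dexter_fraction": fret.dexter_fraction,
                        "alpha_frac": occ["alpha"],
                        "beta_frac": occ["beta"],
                        "ppii_frac": occ["ppii"],
                        "left_alpha_frac": occ["left_alpha"],
                        "coil_frac": occ["other"],
                        "missing_dihedrals": n_missing,
                        "measured_efficiency": eff_rec.corrected_efficiency,
                        "measured_ccs_A2": mob.ccs,
                        "mean_rg_A": float(
                            np.mean([cm.radius_of_gyration(c) for c in ens.conformers])
                        ),
                        "exchange_acc_mean": float(np.mean(ens.sampler_stats)),
                    }
                )
                if cfg.make_plots:
                    pts = _core_dihedral_points(ens)
                    rama_plot(
                        pts,
                        outdir / f"rama_{tag}.png",
                        references=refs,
                        title=f"{alloform} {z}+ core (17-21)",
                    )
                log.info("%s done in %.1fs", tag, time.time() - t_start)
            except Exception as exc:  # noqa: BLE001 - per-combination isolation
                log.error("%s failed: %s", tag, exc)
                failures.append((tag, str(exc)))
    table = pd.DataFrame(rows).sort_values(["alloform", "charge"]).reset_index(drop=True)
    csv_path = outdir / "study_results.csv"
    with open(csv_path, "w") as fh:
        fh.write(f"# abfret study results, schema={SCHEMA_VERSION}\n")
        table.to_csv(fh, index=False, float_format="%.6g")
    if cfg.make_plots and len(table):
        _ccs_vs_fret_plot(table, outdir / "ccs_vs_fret.png")
    return StudyResult(table=table, failures=failures, output_dir=outdir)


def _ccs_vs_fret_plot(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    alloforms = table["alloform"].unique()
    fig, axes = plt.subplots(
        len(alloforms), 1, figsize=(4.6, 3.2 * len(alloforms)), squeeze=False
    )
    for ax, allo in zip(axes[:, 0], alloforms):
        sub = table[table["alloform"] == allo]
        ax.errorbar(
            sub["fret_mean"],
            sub["ccs_mean_A2"],
            yerr=sub["ccs_sd_A2"],
            xerr=sub["fret_sd"],
            fmt="o",
            color="crimson",
            capsize=3,
        )
        for _, row in sub.iterrows():
            ax.annotate(
                f"{int(row['charge'])}+",
                (row["fret_mean"], row["ccs_mean_A2"]),
                textcoords="offset points",
                xytext=(6, 4),
                fontsize=8,
            )
        ax.set_xlabel("FRET efficiency")
        ax.set_ylabel(r"CCS ($\AA^2$)")
        ax.set_title(allo)
        ax.invert_xaxis()  # extension grows to the right
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
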