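"""Configuration, table IO and the command-line interface.

Internally the package works in SI units (m, s, Pa, J); configuration and
tables accept the units the biology is reported in (um, min, Pa) and
convert at the boundary.  Every run emits a provenance record (config
echo, package version, seed, slenderness convention, energy calibration)
sufficient to reproduce its outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import sys

import click
import pandas as pd
import yaml

from wormrod import __version__
from wormrod.cross_section import SectionGeometry, MaterialMap
from wormrod.dissipation import (MuscleTorqueParams, RotationEnvironment,
                                 torque_report)
from wormrod.early_elongation import (MyosinParams, fit_myosin,
                                      g0_lambda_curve, solve_prestrain,
                                      predict_radius)
from wormrod.late_elongation import (CycleSchedule, mutant_scenario,
                                     simulate_late_phase)
from wormrod.rod_reduction import ActivationState, rod_solve
from wormrod.synthetic_data import NoiseSpec, gen_early_series, gen_late_series

__all__ = ["RunConfig", "read_table", "write_table", "cli"]

_SCHEMAS = {
    "early": ["t_min", "lambda", "g0_obs", "radius_obs_um"],
    "late": ["t_min", "length_obs_um"],
    "late_full": ["t_min", "length_um", "cycle_index", "Wc_J", "Wr_J",
                  "delta_zeta_um"],
}

_CONFIG_BLOCKS = {"geometry", "materials", "activation", "schedule",
                  "environment", "myosin", "noise", "output", "seed",
                  "units"}


class RunConfig:
    """Validated run configuration assembled from nested dictionaries."""

    def __init__(self, raw: dict | None = None):
        raw = dict(raw or {})
        unknown = set(raw) - _CONFIG_BLOCKS
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; "
                f"expected a subset of {sorted(_CONFIG_BLOCKS)}")
        units = raw.get("units", {})
        for dim, expected in (("length", "um"), ("time", ("s", "min")),
                              ("modulus", "Pa")):
            if dim in units:
                ok = units[dim] in expected if isinstance(expected, tuple) \
                    else units[dim] == expected
                if not ok:
                    raise ValueError(
                        f"unsupported unit {units[dim]!r} for {dim}")
        self.raw = raw
        self.seed = int(raw.get("seed", 0))
        self.geometry = SectionGeometry(**raw.get("geometry", {}))
        self.materials = MaterialMap(**raw.get("materials", {}))
        self.myosin = MyosinParams(**raw.get("myosin", {}))
        self.activation = ActivationState(**raw.get("activation", {}))
        self.schedule = CycleSchedule(**raw.get("schedule", {}))
        self.environment = RotationEnvironment(**raw.get("environment", {}))
        self.noise = NoiseSpec(**{"seed": self.seed,
                                  **raw.get("noise", {})})

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            if str(path).endswith((".yml", ".yaml")):
                return cls(yaml.safe_load(fh) or {})
            return cls(json.load(fh))

    def provenance(self) -> dict:
        blob = json.dumps(self.raw, sort_keys=True, default=str)
        return {
            "version": __version__,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "eps_convention": self.geometry.eps,
            "config": self.raw,
        }


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV table and validate it against a named schema.

    Raises a schema error naming the offending column on mismatch, and an
    explicit error on empty input or non-numeric (e.g. comma-decimal)
    values -- never silent corruption.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty table")
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} "
                         f"for schema {schema!r}")
    out = df[_SCHEMAS[schema]].copy()
    for col in out.columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        if coerced.isna().any() and not out[col].isna().any():
            raise ValueError(
                f"{path}: column {col!r} contains non-numeric values "
                "(locale decimal commas are not accepted)")
        out[col] = coerced
    return out


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a CSV table (full float precision, '.' decimal, no index)."""
    if schema is not None:
        missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s) {missing} for {schema!r}")
        df = df[_SCHEMAS[schema]]
    df.to_csv(path, index=False, float_format="%.17g")


def _emit(payload: dict, out):
    text = json.dumps(payload, indent=2, default=float)
    if out:
        with open(out, "w") as fh:
            fh.write(text + "\n")
    else:
        click.echo(text)


@click.group()
def cli():
    """Morphoelastic rod model of C. elegans embryonic elongation."""


@cli.command("early-fit")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--lam", type=float, default=1.8, show_default=True,
              help="Axial elongation at which to solve the pre-strain.")
@click.option("--out", type=click.Path(), default=None)
def early_fit(config_path, lam, out):
    """Solve the early-phase pre-strain and radius at an elongation."""
    cfg = RunConfig.from_file(config_path) if config_path else RunConfig()
    g0 = solve_prestrain(lam, cfg.geometry, cfg.materials, cfg.myosin)
    radius = predict_radius(lam, cfg.geometry, cfg.materials, g0=g0)
    _emit({"lambda": lam, "g0": g0, "radius_um": radius,
           "c": (g0 - 1.0) / cfg.geometry.eps,
           "provenance": cfg.provenance()}, out)


@cli.command("myosin-fit")
@click.argument("table", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default=None)
def myosin_fit(table, out):
    """Fit (p1, p3) of the myosin balance to an observed g0(t) table."""
    df = read_table(table, "early")
    fit = fit_myosin(df["t_min"], df["g0_obs"])
    _emit({"p1": fit["p1"], "p3": fit["p3"],
           "residual_rms": fit["residual"]}, out)


@cli.command("rod-solve")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--gm", type=float, default=None)
@click.option("--ga", type=float, default=None)
@click.option("--alpha-a", type=float, default=None)
@click.option("--side", type=click.Choice(["left", "right", "both", "none"]),
              default=None)
@click.option("--out", type=click.Path(), default=None)
def rod_solve_cmd(config_path, gm, ga, alpha_a, side, out):
    """Reduce the activated section to rod loads and intrinsic strains."""
    cfg = RunConfig.from_file(config_path) if config_path else RunConfig()
    act = cfg.activation
    overrides = {k: v for k, v in
                 (("gm", gm), ("ga", ga), ("alpha_a", alpha_a),
                  ("muscle_side", side)) if v is not None}
    if overrides:
        from dataclasses import replace
        act = replace(act, **overrides)
    coeffs, strains = rod_solve(cfg.geometry, cfg.materials, act)
    _emit({"K": {"K0_N": coeffs.K0, "K1_Nm2": coeffs.K1,
                 "K2_Nm2": coeffs.K2, "K3_Nm2": coeffs.K3},
           "H": {"H0_N": coeffs.H0, "H1_Nm": coeffs.H1,
                 "H2_Nm": coeffs.H2, "H3_Nm": coeffs.H3},
           "zeta_hat": strains.zeta_hat,
           "u_hat_per_m": list(strains.u_hat),
           "kappa_hat_per_m": strains.kappa_hat,
           "tau_hat_per_m": strains.tau_hat,
           "provenance": cfg.provenance()}, out)


@cli.command("late-simulate")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--scenario",
              type=click.Choice(["wild_type", "unc112", "spc1_pak1"]),
              default="wild_type", show_default=True)
@click.option("--out", type=click.Path(), default=None,
              help="CSV output path for the per-cycle table.")
def late_simulate(config_path, scenario, out):
    """Simulate the cyclic late-elongation phase."""
    cfg = RunConfig.from_file(config_path) if config_path else None
    schedule = cfg.schedule if (cfg and "schedule" in cfg.raw) \
        else mutant_scenario(scenario)
    res = simulate_late_phase(schedule)
    frame = res.to_frame()
    if out:
        write_table(frame, out)
        click.echo(json.dumps({
            "final_length_um": res.final_length,
            "energy_scale": res.energy_scale,
            "energy_loss_J": res.energy_loss(),
            "n_cycles": schedule.n_cycles}, default=float))
    else:
        click.echo(frame.to_csv(index=False))


@cli.command("dissipation")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--out", type=click.Path(), default=None)
def dissipation_cmd(config_path, out):
    """Torque and dissipated-energy report for the rotating embryo."""
    cfg = RunConfig.from_file(config_path) if config_path else RunConfig()
    params = MuscleTorqueParams(mu_muscle=cfg.materials.mu_muscle,
                                sm=cfg.geometry.sm, pm=cfg.geometry.pm)
    _emit(torque_report(params, cfg.environment), out)


@cli.command("synth")
@click.option("--kind", type=click.Choice(["early", "late"]),
              default="early", show_default=True)
@click.option("--scenario",
              type=click.Choice(["wild_type", "unc112", "spc1_pak1"]),
              default="wild_type", show_default=True)
@click.option("--sigma", type=float, default=0.02, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def synth(kind, scenario, sigma, seed, out):
    """Generate a synthetic observation table (CSV + seed sidecar)."""
    noise = NoiseSpec(sigma=sigma, seed=seed)
    if kind == "early":
        df = gen_early_series(noise=noise)
    else:
        df = gen_late_series(scenario, noise=noise)
    df.to_csv(out, index=False)
    with open(str(out) + ".json", "w") as fh:
        json.dump({"kind": kind, "scenario": scenario, "sigma": sigma,
                   "seed": seed, "version": __version__}, fh, indent=2)
    click.echo(f"wrote {out}")


if __name__ == "__main__":
    cli(sys.argv[1:])
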