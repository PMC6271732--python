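"""Reproduction recipes: one entry point per figure-style study.

Each recipe regenerates the corresponding dataset from scratch (kernels,
slice profiles, spectra, cube fields, scan tables), writes plain-text
artifacts into an output directory and returns a manifest dictionary
(also written as JSON).  Deterministic given its configuration; outputs
are never overwritten unless ``overwrite=True``.

Recipe ids:

* ``fig1``   — square-well kernels over the Nocc panel set + locality trend
* ``fig2_3`` — square-well slice profiles at r' in {0.5, 0.6, 0.8}, Nocc 1 and 50
* ``fig4``   — double-well spectra and pair census for V0 in {25, 100}
* ``fig5_6`` — double-well kernels over the Nocc panel sets
* ``fig7``   — H2 / He2(2+) / He2 response fields as cube files
* ``fig8_9`` — H2 dissociation scan table (restricted vs unrestricted)
* ``fig12``  — butane vs butadiene response cubes + junction audit
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io import export_matrix, export_metrics, export_slice, export_spectrum
from .lrf import TruncationRule, locality_metrics, lrf_matrix, response_slice
from .wells import WellSpec, count_pairs_below_barrier, dw_states, isw_states

RECIPE_IDS = ("fig1", "fig2_3", "fig4", "fig5_6", "fig7", "fig8_9", "fig12")


@dataclass(frozen=True)
class RecipeSpec:
    recipe: str
    outdir: str = "nearsight_out"
    overrides: dict = field(default_factory=dict)
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.recipe not in RECIPE_IDS:
            raise ValueError(f"unknown recipe {self.recipe!r}; known: {RECIPE_IDS}")


def _outdir(spec: RecipeSpec) -> Path:
    out = Path(spec.outdir) / spec.recipe
    if out.exists() and any(out.iterdir()) and not spec.overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite to replace it")
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_recipe(spec: RecipeSpec) -> dict:
    t0 = time.time()
    out = _outdir(spec)
    ov = spec.overrides
    steps: dict = {}
    fn = {
        "fig1": _fig1,
        "fig2_3": _fig2_3,
        "fig4": _fig4,
        "fig5_6": _fig5_6,
        "fig7": _fig7,
        "fig8_9": _fig8_9,
        "fig12": _fig12,
    }[spec.recipe]
    try:
        steps = fn(out, ov)
        status = "ok"
    except Exception as exc:  # manifest records partial failure
        steps["error"] = f"{type(exc).__name__}: {exc}"
        status = "failed"
    manifest = {
        "recipe": spec.recipe,
        "version": __version__,
        "status": status,
        "overrides": ov,
        "wall_time_s": round(time.time() - t0, 2),
        "steps": steps,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    if status == "failed":
        raise RuntimeError(f"recipe {spec.recipe} failed: {steps['error']}")
    return manifest


def _rule(ov: dict) -> TruncationRule:
    return TruncationRule(tau=float(ov.get("tau", 1e-8)), jmax_cap=int(ov.get("jmax_cap", 2000)))


def _fig1(out: Path, ov: dict) -> dict:
    nocc_set = ov.get("nocc_set", (1, 2, 3, 4, 5, 10, 20, 35, 50))
    d = float(ov.get("d", 0.2))
    sp = isw_states(float(ov.get("L", 1.0)), int(ov.get("nmax", 150)))
    trend = {}
    for nocc in nocc_set:
        K = lrf_matrix(sp, nocc, rule=_rule(ov), prefactor=float(ov.get("prefactor", 4.0)))
        export_matrix(K, "text", out / f"lrf_nocc{nocc}.tsv")
        trend[nocc] = locality_metrics(K, d).as_dict()
    export_metrics(trend, out / "locality_trend.json")
    return {"kernels": len(trend), "offrange_mass": {n: trend[n]["offrange_mass"] for n in trend}}


def _fig2_3(out: Path, ov: dict) -> dict:
    r_primes = ov.get("r_primes", (0.5, 0.6, 0.8))
    sp = isw_states(1.0, int(ov.get("nmax", 150)))
    written = []
    for nocc in ov.get("nocc_set", (1, 50)):
        K = lrf_matrix(sp, nocc, rule=_rule(ov))
        for rp in r_primes:
            r, col, used = response_slice(K, rp)
            name = f"slice_nocc{nocc}_rp{rp}.tsv"
            export_slice(r, col, out / name, used)
            written.append(name)
    return {"profiles": written}


def _fig4(out: Path, ov: dict) -> dict:
    res = {}
    for v0 in ov.get("v0_set", (25.0, 100.0)):
        spec = WellSpec(kind="double_well", V0=float(v0), units=ov.get("units", "hbar_me_1"))
        sp = dw_states(spec, int(ov.get("nmax", 20)))
        export_spectrum(sp, out / f"spectrum_v0_{v0:g}.tsv")
        census = count_pairs_below_barrier(sp)
        res[f"V0={v0:g}"] = {"pairs_below_barrier": census.n_pairs, "splittings": list(census.splittings)}
    export_metrics(res, out / "pair_census.json")
    return res


def _fig5_6(out: Path, ov: dict) -> dict:
    counts = {}
    for v0 in ov.get("v0_set", (25.0, 100.0)):
        spec = WellSpec(kind="double_well", V0=float(v0))
        sp = dw_states(spec, int(ov.get("nmax", 400)))
        for nocc in ov.get("nocc_set", (1, 2, 3, 4, 5, 10)):
            K = lrf_matrix(sp, nocc, rule=_rule(ov))
            export_matrix(K, "text", out / f"lrf_v0_{v0:g}_nocc{nocc}.tsv")
            counts[f"V0={v0:g},nocc={nocc}"] = K.m_truncated[-1]
    return {"kernels": len(counts), "m_truncated": counts}


def _fig7(out: Path, ov: dict) -> dict:
    from .qm.cube import write_cube
    from .qm.engines import run_scf
    from .qm.molecules import h2, he2
    from .qm.moset import homo_lumo_gap
    from .qm.response import SitePerturbation, lcao_response
    from .qm.scf import Method

    method = Method(basis=ov.get("basis", "6-31g**"))
    engine = ov.get("engine", "internal")
    pert = SitePerturbation(atom_index=1, form=ov.get("perturbation", "mulliken"))
    res = {}
    systems = {
        "h2": (h2(0.72), 0),
        "he2_2plus": (he2(3.0), 2),
        "he2": (he2(3.0), 0),
    }
    for name, (atoms, charge) in systems.items():
        mos = run_scf(atoms, charge=charge, method=method, engine=engine)
        f = lcao_response(mos, pert)
        write_cube(f, out / f"{name}.cube", atoms=mos.atoms, comment=f"LRF field {name}")
        gap = homo_lumo_gap(mos)
        res[name] = {
            "homo": gap.homo,
            "lumo": gap.lumo,
            "gap": gap.gap,
            "field_l1": f.l1_norm(),
            "field_max": f.max_abs(),
        }
    export_metrics(res, out / "summary.json")
    return res


def _fig8_9(out: Path, ov: dict) -> dict:
    from .qm.response import dissociation_scan
    from .qm.scf import Method

    r_list = ov.get("r_list", (0.8, 1.5, 2.2, 2.5, 3.5))
    scan = dissociation_scan(r_list, method=Method(basis=ov.get("basis", "6-31g**")),
                             engine=ov.get("engine", "internal"))
    with open(out / "scan.tsv", "w") as fh:
        fh.write("# R_angstrom\trestricted_magnitude\tunrestricted_magnitude\tbroken_symmetry\n")
        for k, r in enumerate(scan.r_values):
            fh.write(
                f"{r:.3f}\t{scan.restricted_magnitude[k]:.8e}\t"
                f"{scan.unrestricted_magnitude[k]:.8e}\t{int(scan.broken_symmetry[k])}\n"
            )
    return {
        "r_values": list(map(float, scan.r_values)),
        "restricted": list(map(float, scan.restricted_magnitude)),
        "unrestricted": list(map(float, scan.unrestricted_magnitude)),
        "broken": list(map(bool, scan.broken_symmetry)),
        "errors": {f"{k[0]}:{k[1]}": v for k, v in scan.errors.items()},
    }


def _fig12(out: Path, ov: dict) -> dict:
    from .qm.cube import write_cube
    from .qm.engines import run_scf
    from .qm.molecules import butadiene, butane
    from .qm.response import SitePerturbation, junction_audit, lcao_response
    from .qm.scf import Method

    method = Method(basis=ov.get("basis", "6-31g"), n_radial=int(ov.get("n_radial", 60)),
                    n_theta=int(ov.get("n_theta", 14)))
    engine = ov.get("engine", "internal")
    pert = SitePerturbation(atom_index=0, form=ov.get("perturbation", "mulliken"))
    res = {}
    for name, atoms in (("butane", butane()), ("butadiene", butadiene())):
        mos = run_scf(atoms, method=method, engine=engine)
        f = lcao_response(mos, pert)
        write_cube(f, out / f"{name}.cube", atoms=mos.atoms, comment=f"LRF field {name}")
        res[name] = {
            "far_fraction": junction_audit(mos, pert, far_atoms={2, 3}, field_in=f),
            "field_l1": f.l1_norm(),
        }
    export_metrics(res, out / "junction_audit.json")
    return res
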