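"""Benchmark harnesses and chelation-equilibrium analysis.

Structure-prediction benchmarks: side-chain (rotamer) recovery after
repack-all, sequence recovery by per-position single-point scans, and
stability ddG correlation against experimental mutant tables.

Copper-chelation analysis: the competitive Zincon exchange equilibrium
(exchange constant Kex and derived design dissociation constant
Kd_des = Kd_CuZI / Kex, with Kd_CuZI = 4.68e-17 M at pH 7.4) and
first-order copper-release kinetics (Cu_bound(t) = Cu0 * exp(-Koff t)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import chem, samplers
from .constants import KD_CU_ZINCON, R_KJ, ZINCON_EPSILON
from .engine import Weights
from .params import ONE_TO_THREE


# ---------------------------------------------------------------------------
# torsion helpers
# ---------------------------------------------------------------------------

def circular_difference(a: float, b: float) -> float:
    """Absolute circular difference of two angles in degrees, in [0, 180]."""
    d = abs((a - b + 180.0) % 360.0 - 180.0)
    return float(d)


def torsion_correct(native: float, predicted: float, tol: float = 40.0,
                    period: float = 360.0) -> bool:
    """Whether a predicted torsion is within +/-tol of the native one
    (closed bound), modulo the group's symmetry period."""
    if np.isnan(native) or np.isnan(predicted):
        return False
    d = circular_difference(native, predicted)
    if period < 360.0:
        d = min(d, circular_difference(native + period, predicted))
    return d <= tol


# ---------------------------------------------------------------------------
# rotamer and sequence recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    chi1_accuracy: float                #: percent
    chi12_accuracy: float               #: percent
    chi1_accuracy_core: float | None
    chi12_accuracy_core: float | None
    records: list[dict] = field(default_factory=list)


def _residue_sasa(structure) -> np.ndarray:
    """Per-residue side-chain solvent-accessible surface area (A^2),
    Shrake-Rupley with a 1.4 A probe."""
    import biotite.structure as bst
    arr = structure.to_atom_array()
    try:
        per_atom = bst.sasa(arr, probe_radius=1.4, point_number=200)
    except Exception:
        per_atom = bst.sasa(arr, probe_radius=1.4)
    per_atom = np.nan_to_num(per_atom)
    out = np.zeros(len(structure))
    k = 0
    for i, res in enumerate(structure.residues):
        for a in res.atoms:
            if a.name not in chem.BACKBONE_SET:
                out[i] += per_atom[k]
            k += 1
    return out


def rotamer_recovery(structure, library, weights: Weights | None = None,
                     max_lj: float = 5.0, rounds: int = 10,
                     buried_cutoff: float = 5.0) -> RecoveryReport:
    """Repack all side chains (10 N->C rounds) and compare chi1/chi2
    torsions to the native ones within +/-40 degrees (circular; symmetric
    terminal groups compared modulo their period).

    Residues without a chi1 (Gly/Ala) are excluded from denominators.
    Core residues are those with native side-chain SASA below 5 A^2.
    """
    native_sasa = _residue_sasa(structure)
    result = samplers.repack_all(structure, library, weights, max_lj, rounds)
    repacked = result.structure
    records = []
    for i in structure.interior_indices():
        res = structure[i]
        nchi = chem.n_chi(res.name)
        if nchi == 0:
            continue
        nat = chem.measure_chis(res.coord_lookup(), res.name)
        pred = chem.measure_chis(repacked[i].coord_lookup(), res.name)
        period1 = 360.0 if nchi > 1 else chem.CHI_SYMMETRY.get(res.name, 360.0)
        chi1_ok = torsion_correct(nat[0], pred[0], period=period1)
        chi2_ok = None
        if nchi >= 2:
            period2 = chem.CHI_SYMMETRY.get(res.name, 360.0)
            chi2_ok = torsion_correct(nat[1], pred[1], period=period2)
        records.append({
            "position": i, "aa": res.name, "native": nat, "predicted": pred,
            "chi1_ok": chi1_ok, "chi2_ok": chi2_ok,
            "buried": bool(native_sasa[i] < buried_cutoff),
        })

    def _pct(rs, key):
        vals = [r[key] for r in rs if r[key] is not None]
        return 100.0 * np.mean(vals) if vals else None

    def _pct12(rs):
        vals = [(r["chi1_ok"] and r["chi2_ok"]) for r in rs
                if r["chi2_ok"] is not None]
        return 100.0 * np.mean(vals) if vals else None

    core = [r for r in records if r["buried"]]
    return RecoveryReport(
        chi1_accuracy=_pct(records, "chi1_ok") or 0.0,
        chi12_accuracy=_pct12(records) or 0.0,
        chi1_accuracy_core=_pct(core, "chi1_ok"),
        chi12_accuracy_core=_pct12(core),
        records=records,
    )


def sequence_recovery(structure, library, weights: Weights | None = None,
                      max_lj: float = 10.0, target_aas=None):
    """Percent of positions at which the lowest-energy amino acid from a
    per-position single-point scan equals the native one.

    Terminal residues are excluded; unscoreable positions are excluded
    from the denominator (listed in the report).  Returns (percent or
    None, records).
    """
    if target_aas is None:
        target_aas = sorted(ONE_TO_THREE.values())
    records = []
    hits, n = 0, 0
    for i in structure.interior_indices():
        native = structure[i].name
        try:
            sp = samplers.single_point(structure, i, target_aas, library,
                                       weights, max_lj)
        except samplers.SamplerError:
            records.append({"position": i, "native": native, "best": None,
                            "flag": "unscoreable"})
            continue
        best = min(sp.energies.items(), key=lambda kv: (kv[1], kv[0]))[0]
        records.append({"position": i, "native": native, "best": best,
                        "flag": None})
        n += 1
        hits += int(best == native)
    pct = 100.0 * hits / n if n else None
    return pct, records


def ddg_benchmark(mutants, structure, library, weights: Weights | None = None,
                  max_lj: float = 10.0):
    """Predict ddG for a mutant table and correlate with experiment.

    ``mutants`` is an iterable of (position, wt_one_letter, mut_one_letter,
    ddg_exp) with 0-based positions.  Returns a dict with the Pearson R,
    its two-sided p-value, per-mutant predictions, and excluded mutants.
    """
    preds, exps, rows, excluded = [], [], [], []
    cache: dict[int, samplers.SinglePointResult] = {}
    for pos, wt, mut, ddg_exp in mutants:
        wt3 = ONE_TO_THREE.get(str(wt).upper())
        mut3 = ONE_TO_THREE.get(str(mut).upper())
        if (wt3 is None or mut3 is None or pos < 0 or pos >= len(structure)
                or structure[pos].name != wt3
                or pos not in structure.interior_indices()):
            excluded.append((pos, wt, mut, "unresolvable"))
            continue
        if pos not in cache:
            try:
                cache[pos] = samplers.single_point(
                    structure, pos, sorted(ONE_TO_THREE.values()), library,
                    weights, max_lj)
            except samplers.SamplerError as err:
                excluded.append((pos, wt, mut, str(err)))
                continue
        sp = cache[pos]
        if mut3 not in sp.ddg:
            excluded.append((pos, wt, mut, "no rotamers for mutant"))
            continue
        preds.append(sp.ddg[mut3])
        exps.append(float(ddg_exp))
        rows.append({"position": pos, "wt": wt, "mut": mut,
                     "ddg_pred": sp.ddg[mut3], "ddg_exp": float(ddg_exp)})
    if len(preds) >= 2 and np.std(preds) > 0 and np.std(exps) > 0:
        r, p = stats.pearsonr(preds, exps)
    else:
        r, p = float("nan"), float("nan")
    return {"pearson_r": float(r), "p_value": float(p), "n": len(preds),
            "predictions": rows, "excluded": excluded}


# ---------------------------------------------------------------------------
# copper chelation
# ---------------------------------------------------------------------------

@dataclass
class ChelationFit:
    kex: float | None = None            #: exchange constant (dimensionless)
    kd_des: float | None = None         #: design dissociation constant (M)
    koff: float | None = None           #: release rate constant (1/h)
    cu0_bound: float | None = None      #: percent bound at t = 0
    residuals: np.ndarray | None = None
    flagged: list = field(default_factory=list)


def cu_zincon_concentration(absorbance: float, path_cm: float = 1.0) -> float:
    """[Cu2+:ZI] from the 599 nm absorbance (Beer-Lambert, eps = 26100)."""
    return absorbance / (ZINCON_EPSILON * path_cm)


def kex_of_concentrations(zi_free, cu_des, cu_zi, des_free) -> float:
    """Exchange constant from the four species concentrations."""
    return (zi_free * cu_des) / (cu_zi * des_free)


def _cu_zi_from_kex(kex, zi_tot, cu_tot, des_tot):
    """Equilibrium [Cu2+:ZI] for given totals: positive root of the
    exchange quadratic."""
    # Kex * x * (des_tot - cu_tot + x) = (zi_tot - x)(cu_tot - x)
    a = kex - 1.0
    b = kex * (des_tot - cu_tot) + zi_tot + cu_tot
    c = -zi_tot * cu_tot
    if abs(a) < 1e-12:
        x = -c / b
    else:
        disc = b * b - 4.0 * a * c
        x = (-b + np.sqrt(disc)) / (2.0 * a)
        if not (0.0 < x <= min(zi_tot, cu_tot) + 1e-30):
            x = (-b - np.sqrt(disc)) / (2.0 * a)
    return x


def fit_kex(absorbances, zincon_tot, cu_tot, des_tot, path_cm: float = 1.0
            ) -> ChelationFit:
    """Fit the exchange constant to a Zincon competition titration.

    Each sample carries a known total Zincon, copper, and designed-protein
    concentration (M) plus the 599 nm absorbance.  [Cu2+:ZI] follows from
    Beer-Lambert; the remaining species from the mass balances (free
    copper is negligible under the assay's tight-binding conditions).
    Kex is fitted by least squares on log-concentration residuals over
    the titration; Kd_des = Kd_CuZI / Kex.

    Samples whose absorbance implies more complex than total copper are
    flagged and excluded.
    """
    absorbances = np.atleast_1d(np.asarray(absorbances, dtype=float))
    zincon_tot = np.broadcast_to(np.asarray(zincon_tot, dtype=float),
                                 absorbances.shape).copy()
    cu_tot = np.broadcast_to(np.asarray(cu_tot, dtype=float),
                             absorbances.shape).copy()
    des_tot = np.broadcast_to(np.asarray(des_tot, dtype=float),
                              absorbances.shape).copy()
    cu_zi = absorbances / (ZINCON_EPSILON * path_cm)
    flagged = [i for i in range(len(cu_zi)) if cu_zi[i] > cu_tot[i] * (1 + 1e-9)]
    keep = np.array([i not in flagged for i in range(len(cu_zi))])
    keep &= des_tot > 0
    cu_zi, zt, ct, dt = cu_zi[keep], zincon_tot[keep], cu_tot[keep], des_tot[keep]
    if cu_zi.size == 0:
        return ChelationFit(flagged=flagged)

    # Direct per-sample estimates seed the least-squares fit.
    zi_free = zt - cu_zi
    cu_des = ct - cu_zi
    des_free = dt - cu_des
    ok = (zi_free > 0) & (cu_des > 0) & (des_free > 0)
    k0 = float(np.median(kex_of_concentrations(
        zi_free[ok], cu_des[ok], cu_zi[ok], des_free[ok]))) if ok.any() else 1.0

    def resid(logk):
        k = np.exp(logk[0])
        model = np.array([_cu_zi_from_kex(k, z, c, d)
                          for z, c, d in zip(zt, ct, dt)])
        return np.log(np.clip(model, 1e-300, None)) - np.log(np.clip(cu_zi, 1e-300, None))

    sol = optimize.least_squares(resid, x0=[np.log(max(k0, 1e-12))],
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    kex = float(np.exp(sol.x[0]))
    return ChelationFit(kex=kex, kd_des=KD_CU_ZINCON / kex,
                        residuals=sol.fun, flagged=flagged)


def kd_des_from_kex(kex: float) -> float:
    """Design dissociation constant from the exchange constant."""
    if kex <= 0:
        raise ValueError("Kex must be positive")
    return KD_CU_ZINCON / kex


def fit_koff(t_hours, percent_bound) -> ChelationFit:
    """Fit first-order release kinetics Cu_bound(t) = Cu0 * exp(-Koff t).

    Needs at least three time points.  Non-decaying data returns Koff ~ 0
    with a flag.
    """
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(percent_bound, dtype=float)
    if t.size < 3:
        raise ValueError("need at least three time points")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")

    def model(tt, cu0, koff):
        return cu0 * np.exp(-koff * tt)

    slope_guess = 0.01
    if np.ptp(t) > 0 and np.all(y > 0):
        slope, _ = np.polyfit(t, np.log(y), 1)
        slope_guess = max(-slope, 1e-9)
    popt, _ = optimize.curve_fit(model, t, y,
                                 p0=[max(y.max(), 1e-6), slope_guess],
                                 bounds=([0, 0], [np.inf, np.inf]),
                                 maxfev=20000)
    cu0, koff = float(popt[0]), float(popt[1])
    fit = ChelationFit(koff=koff, cu0_bound=cu0,
                       residuals=y - model(t, *popt))
    if koff * max(np.max(t), 1.0) < 1e-6:  # no measurable decay over the series
        fit.flagged.append("non-decaying data; Koff ~ 0")
    return fit


def binding_efficiency(kd: float, mw_kda: float, temperature: float = 298.0
                       ) -> float:
    """Protein efficiency dG_bind / MW in kJ/kDa.

    dG_bind = R T ln Kd with R = 8.314e-3 kJ/(mol K); negative for
    sub-molar Kd.
    """
    if kd <= 0 or mw_kda <= 0:
        raise ValueError("Kd and MW must be positive")
    return R_KJ * temperature * float(np.log(kd)) / mw_kda
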