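"""End-to-end synthetic benchmark experiments for the pipeline.

Each function regenerates a simulated experiment under the study conditions
the pipeline targets (sampling grids, replicate counts, noise levels), runs
the corresponding analysis stage from scratch, and reports how well it
recovers the generative ground truth. They back both the acceptance test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import detrend_moving_average
from .regimes import constant_darkness, pulse_protocol, reentrainment_protocol, screen_regime
from .rhythm import compute_phase_shift, estimate_period_phase, reentrainment_call
from .photoresponse import build_action_spectrum, pathway_difference_spectrum
from .screen import ScreenThresholds, screen_plate
from .simulate import PlateDesign, WellSpec, simulate_circadian_trace, simulate_plate
from .stats import student_t_test
from .strains import CSL_PATHWAY, DEFAULT_WAVELENGTHS, get_preset
from .traceset import TraceSet


def _single_well_ts(t: np.ndarray, y: np.ndarray, well: str = "w") -> TraceSet:
    counts = pd.DataFrame({well: y}, index=t)
    meta = pd.DataFrame(index=pd.Index([well], name="well"))
    return TraceSet(t, counts, meta)


def detrend_oracle_error(n_traces: int = 100, seed: int = 0) -> float:
    """Max relative deviation of the detrender from a brute-force window mean.

    The oracle recomputes, for every point of every randomized positive
    trace, the plain mean of all samples within +-12 h and the ratio to it.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_traces):
        n = int(rng.integers(60, 200))
        dt = float(rng.uniform(0.25, 1.0))
        t = np.arange(n) * dt
        y = rng.lognormal(3.0, 0.8, n)
        got = detrend_moving_average(_single_well_ts(t, y)).well("w")
        for i in range(n):
            mask = (t >= t[i] - 12.0) & (t <= t[i] + 12.0)
            expected = y[i] / np.mean(y[mask])
            worst = max(worst, abs(got[i] - expected) / abs(expected))
    return worst


def period_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    tau_h: float = 24.0,
    dd_h: float = 120.0,
    sampling_h: float = 0.5,
    noise_cv: float = 0.05,
    tolerance_h: float = 0.3,
) -> dict:
    """Fraction of DD-simulated wells whose estimated period is within tolerance."""
    strain = get_preset("WT-cbr").with_(tau_h=tau_h)
    regime = constant_darkness(dd_h)
    errors = []
    for k in range(n_seeds):
        t, y = simulate_circadian_trace(
            strain, regime, sampling_h, noise_cv, seed=int(seed) * 100003 + k
        )
        dts = detrend_moving_average(_single_well_ts(t, y))
        est = estimate_period_phase(dts)["w"]
        errors.append(est.period_h - tau_h if est.ok else np.inf)
    errors = np.asarray(errors)
    return {
        "fraction_within_tolerance": float((np.abs(errors) <= tolerance_h).mean()),
        "n": n_seeds,
        "abs_error_h": np.abs(errors),
    }


def _translated_pair(delta_h: float, n_rep: int, seed: int, noise_cv: float = 0.05):
    """Control wells plus copies translated so their rhythm leads by delta_h."""
    strain = get_preset("WT-cbr")
    regime = constant_darkness(168.0)
    dt = 0.5
    k = int(round(delta_h / dt))
    control, treated = {}, {}
    t_full = None
    for r in range(n_rep):
        t, y = simulate_circadian_trace(strain, regime, dt, noise_cv, seed=seed * 1009 + r)
        t_full = t
        if k >= 0:  # advance: the treated trace shows later parts earlier
            control[f"c{r}"] = y[: y.size - k] if k else y
            treated[f"t{r}"] = y[k:]
        else:
            control[f"c{r}"] = y[-k:]
            treated[f"t{r}"] = y[: y.size + k]
    t_short = t_full[: t_full.size - abs(k)] if k else t_full
    ts_c = TraceSet(t_short, pd.DataFrame(control, index=t_short),
                    pd.DataFrame(index=pd.Index(list(control), name="well")))
    ts_t = TraceSet(t_short, pd.DataFrame(treated, index=t_short),
                    pd.DataFrame(index=pd.Index(list(treated), name="well")))
    return ts_t, ts_c


def phase_shift_recovery(
    deltas_h=(1.0, 2.0, 5.0), n_rep: int = 4, seed: int = 0
) -> dict:
    """Recovered shift for known translations, and advance/delay antisymmetry."""
    out = {}
    for delta in deltas_h:
        ts_t, ts_c = _translated_pair(delta, n_rep, seed)
        res = compute_phase_shift(
            estimate_period_phase(detrend_moving_average(ts_t)),
            estimate_period_phase(detrend_moving_average(ts_c)),
        )
        out[delta] = res.shift_h
    adv_t, adv_c = _translated_pair(2.0, n_rep, seed + 1)
    dly_t, dly_c = _translated_pair(-2.0, n_rep, seed + 1)
    adv = compute_phase_shift(
        estimate_period_phase(detrend_moving_average(adv_t)),
        estimate_period_phase(detrend_moving_average(adv_c)),
    ).shift_h
    dly = compute_phase_shift(
        estimate_period_phase(detrend_moving_average(dly_t)),
        estimate_period_phase(detrend_moving_average(dly_c)),
    ).shift_h
    out["antisymmetry_residual_h"] = abs(adv + dly)
    return out


def reentrainment_shift(
    preset: str,
    wavelength,
    seed: int,
    n_rep: int = 5,
    noise_cv: float = 0.05,
    advance_h: float = 5.0,
):
    """One simulated re-entrainment plate: advanced LD cycles vs dark control."""
    strain = get_preset(preset)
    treated_reg = reentrainment_protocol(advance_h, 2, wavelength, 2.0, dd_h=120.0)
    control_reg = reentrainment_protocol(advance_h, 2, None, 2.0, dd_h=120.0)
    wells = [
        WellSpec(f"T{r}", strain, treated_reg, r, regime_id="treated") for r in range(n_rep)
    ] + [
        WellSpec(f"C{r}", strain, control_reg, r, regime_id="control") for r in range(n_rep)
    ]
    ts = simulate_plate(PlateDesign(tuple(wells), 0.5, noise_cv, seed=seed))
    dts = detrend_moving_average(ts)
    est = estimate_period_phase(dts, analysis_start_h=treated_reg.dd_start_h() + 12.0)
    treated = {w: e for w, e in est.items() if w.startswith("T")}
    control = {w: e for w, e in est.items() if w.startswith("C")}
    return compute_phase_shift(treated, control)


def reentrainment_calls(n_plates: int = 10, seed: int = 0) -> dict:
    """Re-entrainment hit calls (> 4.5 h) across replicate plates.

    Wild type under 5 h-advanced red cycles should re-entrain (call true);
    the red/violet-pathway knockout should not under red but should under
    blue cycles.
    """
    conditions = {
        "wt_red": ("WT-cbr", 660),
        "csl_red": ("csl-cbr", 660),
        "csl_blue": ("csl-cbr", 460),
    }
    import zlib

    out = {}
    for name, (preset, lam) in conditions.items():
        salt = zlib.crc32(name.encode()) % 1000
        calls, shifts = [], []
        for p in range(n_plates):
            res = reentrainment_shift(preset, lam, seed * 20011 + p * 97 + salt)
            calls.append(reentrainment_call(res))
            shifts.append(res.shift_h)
        out[name] = {
            "true_calls": int(sum(calls)),
            "n_plates": n_plates,
            "mean_shift_h": float(np.mean(shifts)),
        }
    return out


def action_spectrum_plate(
    preset: str,
    n_rep: int = 5,
    noise_cv: float = 0.05,
    seed: int = 0,
    irradiance: float = 0.5,
):
    """Equal-quantum pulse assay over the default wavelength grid."""
    strain = get_preset(preset)
    wells = []
    for lam in DEFAULT_WAVELENGTHS:
        regime = pulse_protocol(3.0, 5 / 60, lam, irradiance, 3.0)
        for r in range(n_rep):
            wells.append(WellSpec(f"{preset}-{lam}-{r}", strain, regime, r))
    ts = simulate_plate(PlateDesign(tuple(wells), 1 / 3, noise_cv, seed=seed))
    return build_action_spectrum(ts, pulse_start_h=3.0, search_window_h=2.0)


def pathway_spectrum_recovery(seed: int = 0) -> dict:
    """WT-minus-knockout difference spectrum vs the generative pathway."""
    wt_spec = action_spectrum_plate("WT", seed=seed * 4049 + 1)
    csl_spec = action_spectrum_plate("csl", seed=seed * 4049 + 2)
    diff = pathway_difference_spectrum(wt_spec, csl_spec)
    generative = [CSL_PATHWAY.relative_action[float(w)] for w in diff.wavelengths_nm]
    r = float(np.corrcoef(generative, diff.sensitivity)[0, 1])
    wt660, csl660 = wt_spec.at(660), csl_spec.at(660)
    return {
        "pearson_r": r,
        "csl_over_wt_at_660": float(csl660 / wt660) if wt660 > 0 else float("nan"),
        "wt_660": float(wt660),
        "csl_660": float(csl660),
    }


def screen_accuracy(n_per_class: int = 50, noise_cv: float = 0.05, seed: int = 0) -> dict:
    """Classifier accuracy over simulated archetype wells, with the
    unconditional (degradation-null) and conditional (history-dependent)
    no-acute-response presets checked explicitly."""
    regime = screen_regime()
    presets = {"WT": "WT-like", "type1": "Type1", "type2": "Type2", "type3": "Type3"}
    wells, labels = [], {}
    for preset in presets:
        strain = get_preset(preset)
        for r in range(n_per_class):
            wid = f"{preset}-{r}"
            wells.append(WellSpec(wid, strain, regime, r))
            labels[wid] = presets[preset]
    ts = simulate_plate(PlateDesign(tuple(wells), 0.25, noise_cv, seed=seed))
    calls = screen_plate(ts, regime, ScreenThresholds())
    correct = sum(labels[w] == c for w, c in zip(calls["well"], calls["class"]))
    type3_rows = calls[[w.startswith("type3") for w in calls["well"]]]
    # noise-free archetype endpoints for the conditionality contract
    roc = simulate_plate(
        PlateDesign((WellSpec("roc114-0", get_preset("roc114"), regime),), 0.25)
    )
    roc_call = screen_plate(roc, regime).iloc[0]
    return {
        "accuracy": correct / len(labels),
        "n_wells": len(labels),
        "type3_conditional_fraction": float(type3_rows["conditional"].mean()),
        "roc114_class": roc_call["class"],
        "roc114_conditional": bool(roc_call["conditional"]),
    }


def stats_agreement(n_pairs: int = 50, seed: int = 0) -> dict:
    """Largest deviation of the in-house t-test from the reference
    implementation over random group pairs."""
    rng = np.random.default_rng(seed)
    worst_t = worst_p = 0.0
    for _ in range(n_pairs):
        a = rng.normal(rng.uniform(-3, 3), rng.uniform(0.5, 2.5), int(rng.integers(3, 12)))
        b = rng.normal(rng.uniform(-3, 3), rng.uniform(0.5, 2.5), int(rng.integers(3, 12)))
        t, _, p = student_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        worst_t = max(worst_t, abs(t - ref.statistic))
        worst_p = max(worst_p, abs(p - ref.pvalue))
    return {"max_t_deviation": worst_t, "max_p_deviation": worst_p, "n_pairs": n_pairs}
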