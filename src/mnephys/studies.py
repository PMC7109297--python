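"""Validation studies: parameter-recovery, mechanism and calibration
experiments run entirely in silico.

Each study generates its own synthetic cells or variables from a seed, runs
the package's extraction or statistics on them, and returns summary
numbers.  They back the package's self-validation (test suite and the
reproduction script) and are part of the public API so the problem sizes
can be varied.

Problem sizes and the integration step of the cohort-level phenotype study
(dt = 0.05 ms, 2.5 s ramp limbs) are chosen to keep the full battery in the
minutes range on one CPU; single-cell accuracy checks use the default
dt = 0.025 ms.
"""

from __future__ import annotations

import warnings

import numpy as np

from .cohort import draw_parameters, severe_shift, sham_distributions
from .features import (analyze_pic, estimate_capacitance, fi_ramp_metrics,
                       fit_leak, rmp_from_ramp)
from .params import MNParameters, passive_parameters
from .protocols import (build_capacitance_step_protocol,
                        build_cclamp_ramp_protocol, build_vclamp_ramp_protocol)
from .simulate import ionic_current_ss, simulate
from .stats import VariableSeries, compare_groups

__all__ = ["passive_recovery_study", "pic_recovery_study",
           "qss_pic_minimum", "delta_i_mechanism_study",
           "null_calibration_study", "phenotype_recovery_study"]


# ---------------------------------------------------------------------------
# passive-property recovery

def passive_recovery_study(n_cells: int = 50, seed: int = 0) -> dict:
    """Simulate passive (leak-only) cells with randomised C, gL, EL and
    recover input resistance, RMP, capacitance and (absent) PIC amplitude.

    Returns per-cell relative/absolute errors of each estimate against the
    generating parameter.
    """
    rng = np.random.default_rng(seed)
    # slow ramp: the capacitive offset C*dV/dt on the descending limb is
    # smallest, so the zero-current crossing sits closest to EL
    vc = build_vclamp_ramp_protocol(-90, 0, 8.0, 8.0, pre_hold=0.25,
                                    post_hold=0.25)
    cap_prot = build_capacitance_step_protocol()
    rin_err, rmp_err, cap_err, pic_amp = [], [], [], []
    for i in range(n_cells):
        C = rng.uniform(120, 320)
        gL = rng.uniform(12, 28)
        EL = rng.uniform(-68, -55)
        p = passive_parameters(C=C, gL=gL, EL=EL)
        s1 = int(rng.integers(0, 2**31 - 1))
        sw = simulate(p, vc, seed=s1)
        leak = fit_leak(sw)
        rin_err.append(abs(leak.input_resistance - 1000.0 / gL) * gL / 1000.0)
        rmp = rmp_from_ramp(sw)
        rmp_err.append(abs(rmp - EL))
        cap = estimate_capacitance(
            simulate(p, cap_prot, seed=s1 + 1))
        cap_err.append(abs(cap - C) / C)
        pic = analyze_pic(sw, C, leak=leak)
        # absent PIC reports NaN amplitude; a detected one would be spurious
        pic_amp.append(0.0 if not pic.present else abs(pic.amplitude))
    return {"rin_rel_err": np.array(rin_err),
            "rmp_abs_err_mV": np.array(rmp_err),
            "cap_rel_err": np.array(cap_err),
            "spurious_pic_amp_pA": np.array(pic_amp)}


# ---------------------------------------------------------------------------
# PIC recovery against the analytic quasi-steady-state oracle

def qss_pic_minimum(p: MNParameters, holding: float = -90.0,
                    peak: float = 0.0,
                    window_offset: tuple[float, float] = (5.0, 25.0),
                    ) -> float:
    """Analytic quasi-steady-state leak-subtracted PIC minimum (pA).

    Evaluates the steady-state I-V on a fine voltage grid, fits the leak
    line over the same window the extractor uses, subtracts it, and returns
    the most negative value — the slow-ramp limit of the measured PIC
    amplitude.
    """
    V = np.linspace(holding, peak, 2001)
    I = ionic_current_ss(p, V)
    lo, hi = holding + window_offset[0], holding + window_offset[1]
    sel = (V >= lo) & (V <= hi)
    coef = np.polyfit(V[sel], I[sel], 1)
    sub = I - np.polyval(coef, V)
    return float(sub.min())


def pic_recovery_study(n_cells: int = 20, seed: int = 0) -> dict:
    """Slow-ramp (11.25 mV/s) PIC amplitude extraction versus the analytic
    quasi-steady-state minimum for cells with non-inactivating NaP/CaL PICs
    (the regime where the quasi-steady-state limit is exact)."""
    rng = np.random.default_rng(seed)
    vc = build_vclamp_ramp_protocol(-90, 0, 8.0, 8.0, pre_hold=0.25,
                                    post_hold=0.25)
    rel_err, extracted, analytic = [], [], []
    for i in range(n_cells):
        p = MNParameters(
            C=rng.uniform(150, 280),
            gL=rng.uniform(14, 24),
            EL=rng.uniform(-65, -58),
            gNaP=rng.uniform(3.0, 7.0),
            V_half_NaP=rng.uniform(-45, -40),
            tau_inact_NaP=np.inf,
            gCaL=rng.uniform(1.0, 5.0),
            gH=0.0,
        )
        sw = simulate(p, vc, seed=int(rng.integers(0, 2**31 - 1)))
        pic = analyze_pic(sw, p.C)
        oracle = qss_pic_minimum(p)
        extracted.append(pic.amplitude)
        analytic.append(oracle)
        rel_err.append(abs(pic.amplitude - oracle) / abs(oracle))
    return {"rel_err": np.array(rel_err),
            "extracted_pA": np.array(extracted),
            "analytic_pA": np.array(analytic)}


# ---------------------------------------------------------------------------
# delta-I mechanism

def delta_i_mechanism_study(n_cells: int = 20, seed: int = 0,
                            dt: float = 0.05) -> dict:
    """Paired in-silico experiment on the sustained-firing mechanism.

    Condition A: fast NaP slow-inactivation (tau = 150 ms) and gCaL = 0.
    Condition B: the same cells with slow inactivation removed
    (tau -> inf) and the L-type conductance enabled (gCaL = 6 nS).
    Returns per-cell delta-I under both conditions.
    """
    cc = build_cclamp_ramp_protocol(900, 3, 3, pre_hold=0.25, post_hold=0.25)
    dists = sham_distributions()
    a_vals, b_vals = [], []
    for i in range(n_cells):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        base = draw_parameters(dists, rng)
        pA = base.replace(gCaL=0.0, tau_inact_NaP=150.0)
        pB = base.replace(gCaL=6.0, tau_inact_NaP=np.inf)
        sA = int(rng.integers(0, 2**31 - 1))
        fiA = fi_ramp_metrics(simulate(pA, cc, seed=sA, dt=dt))
        fiB = fi_ramp_metrics(simulate(pB, cc, seed=sA, dt=dt))
        a_vals.append(fiA.delta_I if fiA.ok else np.nan)
        b_vals.append(fiB.delta_I if fiB.ok else np.nan)
    return {"delta_i_fast_inact": np.array(a_vals),
            "delta_i_sustained": np.array(b_vals)}


# ---------------------------------------------------------------------------
# statistics calibration on null cohorts

def null_calibration_study(n_variables: int = 2000, seed: int = 0,
                           group_sizes: dict[str, int] | None = None,
                           alpha: float = 0.05) -> dict:
    """Type-I behaviour of the gated engine on null variables.

    Every group is drawn from the same normal distribution; for each
    simulated variable the full gate + omnibus + post hoc pipeline runs and
    the severe-vs-sham post hoc and omnibus rejections at ``alpha`` are
    recorded.  The omnibus rejection rate is nominally ``alpha``; the
    Tukey/Dunn-adjusted pairwise contrast is conservative by construction
    (family-wise control), so its rate falls well below ``alpha``.
    """
    if group_sizes is None:
        group_sizes = {"sham": 9, "HI_unaffected": 12,
                       "HI_mild": 10, "HI_severe": 8}
    rng = np.random.default_rng(seed)
    groups = list(group_sizes)
    labels = np.concatenate([[g] * n for g, n in group_sizes.items()])
    rej_post = rej_omni = 0
    routed_parametric = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_variables):
            values = rng.normal(0.0, 1.0, size=len(labels))
            series = VariableSeries("null", values, labels, reference="sham")
            comp = compare_groups(series, alpha=alpha)
            routed_parametric += comp.test == "anova_tukey"
            rej_omni += comp.p_omnibus <= alpha
            rej_post += comp.posthoc_p["HI_severe"] <= alpha
    return {"posthoc_severe_vs_sham_rate": rej_post / n_variables,
            "omnibus_rate": rej_omni / n_variables,
            "parametric_route_fraction": routed_parametric / n_variables,
            "n_variables": n_variables}


# ---------------------------------------------------------------------------
# end-to-end phenotype recovery

def phenotype_recovery_study(n_replicates: int = 100, seed: int = 0,
                             dt: float = 0.05,
                             alpha: float = 0.05) -> dict:
    """Replicated end-to-end test that the pipeline flags the injured
    phenotype: cohorts with the default group shifts and group sizes
    9/12/10/8 are simulated, RMP and delta-I extracted per cell, QC applied,
    and the gated severe-vs-sham post hoc p computed per replicate.

    Uses the two protocols those variables need (fast voltage ramp, current
    ramp) at a coarsened dt; returns the fraction of replicates in which
    each variable is significant (p <= alpha).
    """
    from .cohort import mild_shift

    vc = build_vclamp_ramp_protocol(-90, 0, 2.5, 2.5, pre_hold=0.25,
                                    post_hold=0.25)
    cc = build_cclamp_ramp_protocol(900, 2.5, 2.5, pre_hold=0.25,
                                    post_hold=0.25)
    dists = {
        "sham": sham_distributions(),
        "HI_unaffected": sham_distributions(),
        "HI_mild": {**sham_distributions(), **mild_shift()},
        "HI_severe": {**sham_distributions(), **severe_shift()},
    }
    sizes = {"sham": 9, "HI_unaffected": 12, "HI_mild": 10, "HI_severe": 8}
    sig_rmp = sig_di = 0
    p_rmp_all, p_di_all = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            rmps, dis, labels = [], [], []
            cell = 0
            for g, n in sizes.items():
                for _ in range(n):
                    rng = np.random.default_rng(np.random.SeedSequence(
                        entropy=seed, spawn_key=(rep, cell)))
                    p = draw_parameters(dists[g], rng)
                    s = int(rng.integers(0, 2**31 - 1))
                    rmp = rmp_from_ramp(simulate(p, vc, seed=s, dt=dt))
                    rmp = np.nan if rmp is None else rmp
                    if np.isfinite(rmp) and rmp > -45.0:
                        cell += 1
                        continue    # QC exclusion
                    fi = fi_ramp_metrics(simulate(p, cc, seed=s + 1, dt=dt))
                    rmps.append(rmp)
                    dis.append(fi.delta_I if fi.ok else np.nan)
                    labels.append(g)
                    cell += 1
            labels = np.array(labels)
            p_rmp = compare_groups(VariableSeries(
                "rmp", np.array(rmps), labels)).posthoc_p["HI_severe"]
            p_di = compare_groups(VariableSeries(
                "delta_i", np.array(dis), labels)).posthoc_p["HI_severe"]
            p_rmp_all.append(p_rmp)
            p_di_all.append(p_di)
            sig_rmp += p_rmp <= alpha
            sig_di += p_di <= alpha
    return {"rmp_significant_fraction": sig_rmp / n_replicates,
            "delta_i_significant_fraction": sig_di / n_replicates,
            "p_rmp": np.array(p_rmp_all), "p_delta_i": np.array(p_di_all),
            "n_replicates": n_replicates}
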