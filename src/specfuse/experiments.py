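"""Benchmark experiments on the synthetic study conditions.

These functions reproduce, at desk scale, the qualitative findings the
calibration stack is built around: the spectra-to-spectra ratio improves
full-spectrum PLSR under combined additive/multiplicative scatter; the
wavelength selectors recover planted informative variables; and stacked
fusion of selector members behaves as the combiner theory predicts. They
are used by both the test suite and the reproduction script, with the
study conditions (sample sizes, effect distributions, noise) fixed by the
scenario presets in :mod:`specfuse.simulate`.
"""

from __future__ import annotations

import numpy as np

from .crossval import MCCVConfig, derive_seed
from .evaluation import SplitSpec, evaluate, split_dataset
from .fusion import build_mcmf
from .preprocess import ss_apply, ss_fit
from .regressors import fit_plsr
from .selection import (SelectionConfig, boss_select, cars_select,
                        ivissa_select)
from .simulate import PlantedParams, scenario, simulate, simulate_planted

__all__ = [
    "ss_vs_raw_rmsep",
    "selector_recovery",
    "block_selector_comparison",
    "mcmf_fusion_improvement",
]

#: Monte-Carlo repeats for the reference-wavelength search in experiments;
#: desk-scale (the preprocessing default is 50).
SS_SEARCH_REPEATS = 20


def _split_and_correct(seed: int, max_lvs: int = 15):
    ds, _ = simulate(scenario("both", seed=seed))
    cal, pred = split_dataset(ds, SplitSpec(seed=seed))
    model = ss_fit(cal, mccv=MCCVConfig(n_repeats=SS_SEARCH_REPEATS, seed=seed),
                   max_lvs=max_lvs)
    return cal, pred, ss_apply(cal, model), ss_apply(pred, model)


def ss_vs_raw_rmsep(seeds=(1, 2, 3, 4, 5), max_lvs: int = 15) -> dict:
    """Paired full-spectrum PLSR with and without the S/S correction.

    For each seed: simulate the combined-effects scenario, split 3:1, fit
    PLSR on raw and on spectra-to-spectra corrected spectra (latent
    variables by MCCV in both arms), and record the prediction RMSEPs.
    """
    raw_rmseps, ss_rmseps = [], []
    for seed in seeds:
        cal, pred, calc, predc = _split_and_correct(seed, max_lvs)
        mccv = MCCVConfig(seed=derive_seed(seed, "lv"))
        m_raw = fit_plsr(cal.X, cal.y, max_lvs=max_lvs, mccv=mccv)
        m_ss = fit_plsr(calc.X, calc.y, max_lvs=max_lvs, mccv=mccv)
        raw_rmseps.append(evaluate(cal.y, m_raw.predict(cal.X),
                                   pred.y, m_raw.predict(pred.X)).rmsep)
        ss_rmseps.append(evaluate(calc.y, m_ss.predict(calc.X),
                                  predc.y, m_ss.predict(predc.X)).rmsep)
    return {
        "seeds": list(seeds),
        "raw_rmsep": raw_rmseps,
        "ss_rmsep": ss_rmseps,
        "raw_median": float(np.median(raw_rmseps)),
        "ss_median": float(np.median(ss_rmseps)),
    }


def selector_recovery(algorithm: str = "cars", seeds=tuple(range(1, 11)),
                      n_runs: int | None = None) -> dict:
    """Across-seed selection frequencies on the planted-support scenario.

    Returns per-variable selection counts over the seeds, split into the
    planted (informative) and noise variables.
    """
    select = {"cars": cars_select, "boss": boss_select}[algorithm]
    counts = None
    planted = None
    for seed in seeds:
        ds, truth = simulate(scenario("planted_wavelengths", seed=seed))
        planted = truth["planted"]
        if counts is None:
            counts = np.zeros(ds.n_wavelengths)
        cfg = SelectionConfig(seed=seed, n_runs=n_runs)
        res = select(ds.X, ds.y, cfg)
        counts[res.selected] += 1
    noise = np.setdiff1d(np.arange(counts.size), planted)
    return {
        "algorithm": algorithm,
        "n_seeds": len(seeds),
        "planted": planted.tolist(),
        "planted_counts": counts[planted].tolist(),
        "min_planted_count": float(counts[planted].min()),
        "max_noise_count": float(counts[noise].max()),
    }


BLOCK_PARAMS = dict(planted_starts=(40, 120), block_width=8)


def block_selector_comparison(seed: int = 2, n_runs: int = 100,
                              ivissa_outer: int = 10) -> dict:
    """All three selectors on the planted contiguous-block dataset.

    Reports the selected-subset sizes (the interval-based selector keeps
    substantially more wavelengths) and, for the interval selector, how
    much of each planted block its intervals cover.
    """
    ds, truth = simulate_planted(PlantedParams(seed=seed, **BLOCK_PARAMS))
    sizes = {}
    cfgs = {
        "cars": SelectionConfig(seed=seed),
        "boss": SelectionConfig(seed=seed, n_runs=n_runs),
        "ivissa": SelectionConfig(seed=seed, n_runs=n_runs,
                                  max_outer=ivissa_outer),
    }
    results = {}
    for name, fn in (("cars", cars_select), ("boss", boss_select),
                     ("ivissa", ivissa_select)):
        res = fn(ds.X, ds.y, cfgs[name])
        results[name] = res
        sizes[name] = int(res.selected.size)
    width = BLOCK_PARAMS["block_width"]
    coverage = []
    iv = set(results["ivissa"].selected.tolist())
    for start in BLOCK_PARAMS["planted_starts"]:
        coverage.append(len(iv & set(range(start, start + width))))
    return {"sizes": sizes, "block_width": width,
            "ivissa_block_coverage": coverage,
            "selected": {k: v.selected.tolist() for k, v in results.items()}}


def mcmf_fusion_improvement(seeds=(1, 2, 3, 4, 5), selector_runs: int = 100,
                            ivissa_outer: int = 10) -> dict:
    """MCMF stacking vs its members on the combined-effects scenario.

    For each seed: S/S-corrected calibration, CARS/BOSS/iVISSA member
    subsets, then (a) MLR stacking — calibration RMSE must not exceed any
    member's (exact least-squares property) — and (b) PSO-ELM stacking,
    recording whether the fused prediction RPD reaches the best member's.
    """
    mlr_ok, pso_wins = [], []
    member_rpds_all, fused_rpds = [], []
    for seed in seeds:
        cal, pred, calc, predc = _split_and_correct(seed)
        sel = {
            "CARS": cars_select(calc.X, calc.y, SelectionConfig(seed=seed)),
            "BOSS": boss_select(calc.X, calc.y,
                                SelectionConfig(seed=seed, n_runs=selector_runs)),
            "iVISSA": ivissa_select(calc.X, calc.y,
                                    SelectionConfig(seed=seed,
                                                    n_runs=selector_runs,
                                                    max_outer=ivissa_outer)),
        }
        fm_mlr, _ = build_mcmf(calc, predc, sel, combiner="mlr", seed=seed)
        fused_rmsec = float(np.sqrt(np.mean((fm_mlr.predict(calc.X) - calc.y) ** 2)))
        member_rmsec = [float(np.sqrt(np.mean((m.predict(calc.X) - calc.y) ** 2)))
                        for m in fm_mlr.members]
        mlr_ok.append(fused_rmsec <= min(member_rmsec) + 1e-9)
        fm_pso, preds = build_mcmf(calc, predc, sel, combiner="pso-elm",
                                   seed=seed)
        fused_rpd = evaluate(calc.y, fm_pso.predict(calc.X), predc.y, preds).rpd
        member_rpds = [evaluate(calc.y, m.predict(calc.X), predc.y,
                                m.predict(predc.X)).rpd
                       for m in fm_pso.members]
        member_rpds_all.append(member_rpds)
        fused_rpds.append(float(fused_rpd))
        pso_wins.append(bool(fused_rpd >= max(member_rpds)))
    return {
        "seeds": list(seeds),
        "mlr_calibration_never_worse": mlr_ok,
        "pso_elm_rpd_wins": pso_wins,
        "fused_rpd": fused_rpds,
        "member_rpds": member_rpds_all,
    }
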