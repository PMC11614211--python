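"""Calibration and recovery studies on the synthetic generator.

These are the package's own validation experiments, run end to end through
the public pipeline:

* ``null_calibration`` — effect-free cohorts; the fraction of contacts
  flagged significant estimates the per-contact false-positive rate of the
  binomial decision rule.
* ``cluster_fwer`` — pure-noise observation maps; the fraction of
  repetitions with any significant cluster estimates the family-wise error
  of the sign-flip cluster permutation test.
* ``planted_effect_recovery`` — a cohort with known spectral effects;
  measures sensitivity, false positives, the overlap (Jaccard) between
  recovered cluster masks and the planted band/window, and the maximum
  eigenspectrogram decision-identity error across all fitted folds.
* ``determinism_check`` — two runs of one config; byte-compares the TSVs.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np

from .clusterstats import one_sample_cluster_perm
from .pipeline import RunConfig, run_pipeline
from .synth import MODALITIES, EffectSpec, NoiseModel, SynthConfig

_REGION_CYCLE = [
    "superiortemporal",
    "superiorparietal",
    "inferiorparietal",
    "lingual",
    "fusiform",
    "putamen",
    "precentral",
    "lateraloccipital",
]


def _labels(n: int, special: dict[int, str] | None = None) -> dict[str, str]:
    labels = {}
    for i in range(n):
        labels[f"C{i:03d}"] = (special or {}).get(i, _REGION_CYCLE[i % len(_REGION_CYCLE)])
    return labels


def null_calibration(
    seed: int,
    n_contacts: int = 200,
    cohort_size: int = 25,
    alpha: float = 0.01,
) -> dict:
    """Fraction of effect-free contacts flagged significant (pooled "all"
    contrast) across independent cohorts with the default task schedule."""
    n_cohorts = int(np.ceil(n_contacts / cohort_size))
    n_sig = 0
    n_run = 0
    accs = []
    for c in range(n_cohorts):
        cfg = RunConfig(
            synth=SynthConfig(
                n_contacts=min(cohort_size, n_contacts - n_run),
                region_labels=_labels(min(cohort_size, n_contacts - n_run)),
                seed=0,
            ),
            formats=("all",),
            run_cluster_tests=False,
            alpha=alpha,
            seed=seed * 1000 + c,
        )
        bundle = run_pipeline(cfg)
        for r in bundle.results:
            n_run += 1
            n_sig += int(r.significant)
            accs.append(r.accuracy)
    return {
        "n_contacts": n_run,
        "n_significant": n_sig,
        "fraction_significant": n_sig / n_run,
        "mean_accuracy": float(np.mean(accs)),
    }


def cluster_fwer(
    seed: int,
    n_reps: int = 500,
    n_obs: int = 40,
    shape: tuple[int, int] = (26, 21),
    alpha: float = 0.01,
    n_perm: int = 1000,
) -> dict:
    """Family-wise error of the cluster permutation test on pure-noise maps."""
    rng = np.random.default_rng(seed)
    n_any = 0
    for _ in range(n_reps):
        maps = rng.standard_normal((n_obs,) + shape)
        cs = one_sample_cluster_perm(
            maps, alpha=alpha, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        n_any += int(len(cs.significant_clusters()) > 0)
    return {
        "n_reps": n_reps,
        "n_with_significant_cluster": n_any,
        "fwer": n_any / n_reps,
    }


def recovery_config(seed: int, n_contacts: int = 16) -> RunConfig:
    """16-contact cohort with broadband/alpha/theta effects on 6 contacts."""
    # high-frequency broadband responses are transient; alpha/theta power
    # changes are sustained through the 1-s stimulus
    effect_rows = {
        0: ("superiortemporal", (70.0, 150.0), "increase", (0.0, 0.5)),
        1: ("superiortemporal", (70.0, 150.0), "increase", (0.0, 0.5)),
        2: ("superiorparietal", (8.0, 13.0), "decrease", (0.0, 1.0)),
        3: ("inferiorparietal", (8.0, 13.0), "decrease", (0.0, 1.0)),
        4: ("putamen", (4.0, 8.0), "increase", (0.0, 1.0)),
        5: ("lingual", (4.0, 8.0), "increase", (0.0, 1.0)),
    }
    labels = _labels(n_contacts, {i: r for i, (r, *_rest) in effect_rows.items()})
    effects = tuple(
        EffectSpec(
            contact=f"C{i:03d}",
            modalities=MODALITIES,
            band_hz=band,
            window_s=window,
            direction=direction,
            magnitude=3.0,
        )
        for i, (_, band, direction, window) in effect_rows.items()
    )
    return RunConfig(
        synth=SynthConfig(
            n_contacts=n_contacts,
            region_labels=labels,
            effects=effects,
            noise=NoiseModel(one_over_f_exponent=1.0, amplitude_uv=20.0),
            seed=0,
        ),
        formats=("all",),
        run_cluster_tests=True,
        seed=seed,
    )


def _planted_mask(bundle_result, effect: EffectSpec) -> np.ndarray:
    """Planted band/window in feature space, clipped to the cropped span."""
    feats = bundle_result.model.features
    freqs, times = feats.freqs_hz, feats.times
    mask = np.zeros(feats.grid_shape, dtype=bool)
    f_in = (freqs >= effect.band_hz[0]) & (freqs <= effect.band_hz[1])
    t_in = (times >= effect.window_s[0]) & (times <= effect.window_s[1])
    mask[: len(freqs)][np.ix_(f_in, t_in)] = True
    return mask


def planted_effect_recovery(seed: int, n_contacts: int = 16) -> dict:
    """Run the recovery cohort and score detection and cluster overlap."""
    cfg = recovery_config(seed, n_contacts)
    bundle = run_pipeline(cfg)
    effects = {e.contact: e for e in cfg.synth.effects}
    by_contact = {r.contact: r for r in bundle.results if r.format == "all"}

    hits, false_pos, jaccards = 0, 0, []
    for contact, res in by_contact.items():
        if contact in effects:
            hits += int(res.significant)
        else:
            false_pos += int(res.significant)
    for contact, eff in effects.items():
        cs = bundle.clusters.get((contact, "all"))
        if cs is None:
            jaccards.append(0.0)
            continue
        # contribution maps measure classification evidence, which is
        # positive for reliably discriminative points whatever the sign of
        # the underlying power change, so overlap is scored sign-blind
        rec_mask = cs.significant_mask()
        planted = _planted_mask(by_contact[contact], eff)
        inter = np.sum(rec_mask & planted)
        union = np.sum(rec_mask | planted)
        jaccards.append(float(inter / union) if union else 0.0)

    # eigenspectrogram decision identity, checked on every fold of every fit
    max_err = 0.0
    for res in bundle.results:
        feats = res.model.features
        for cmap, fold in zip(res.eigenspectrograms(), res.folds):
            z = (feats.vectors - fold.feat_mean) / fold.feat_sd
            direct = cmap.decision_values(z)
            via_pca = fold.decision_values(feats.vectors)
            max_err = max(max_err, float(np.max(np.abs(direct - via_pca))))

    n_eff = len(effects)
    n_null = len(by_contact) - n_eff
    return {
        "n_effect_contacts": n_eff,
        "n_null_contacts": n_null,
        "sensitivity": hits / n_eff,
        "false_positive_rate": false_pos / n_null,
        "mean_jaccard": float(np.mean(jaccards)),
        "jaccards": jaccards,
        "eigenspectrogram_max_identity_error": max_err,
        "bundle": bundle,
    }


def determinism_check(seed: int, out_root) -> dict:
    """Run a small synthetic config twice; compare TSV outputs byte-wise."""
    out_root = Path(out_root)
    dirs = [out_root / "run1", out_root / "run2"]
    for d in dirs:
        cfg = RunConfig(
            synth=SynthConfig(n_contacts=4, region_labels=_labels(4), seed=0),
            formats=("arabic", "all"),
            run_cluster_tests=True,
            out_dir=str(d),
            seed=seed,
        )
        run_pipeline(cfg)
    identical = all(
        filecmp.cmp(dirs[0] / name, dirs[1] / name, shallow=False)
        for name in ("summary.tsv", "counts.tsv", "region_accuracy.tsv")
    )
    return {"identical": identical}
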