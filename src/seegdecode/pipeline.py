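"""End-to-end orchestration: synthesize/load -> preprocess -> features ->
decode -> cluster tests -> group maps.

A single :class:`RunConfig` (YAML/JSON serializable) drives the run; a
master seed fans out deterministically to every stage and every
(contact, format) fit, so re-running with an identical config reproduces
every number exactly, including the on-disk TSV summaries byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import io as sio
from .clusterstats import ClusterSet
from .decoder import ContactDecoder, ContactDecoderResults, NullSpec
from .features import EpochFeatureSet, TFRConfig, bandpass_voltage, build_feature_matrix, morlet_power
from .groupmaps import FeatureMapBundle, count_significant, feature_maps, region_accuracy
from .preprocess import (
    ITI,
    STIMULUS,
    EpochSet,
    Recording,
    average_reference,
    drop_bad_epochs,
    estimate_rejection_threshold,
    extract_epochs,
)
from .synth import (
    MODALITIES,
    SynthConfig,
    TaskSchedule,
    build_schedule,
    make_electrode_table,
    simulate_recording,
)

logger = logging.getLogger(__name__)

FORMATS = MODALITIES + ("all",)

# fixed stage keys for the seed fan-out
_STAGE_KEYS = {
    "schedule": 1,
    "recording": 2,
    "epochs": 3,
    "threshold": 4,
    "reject": 5,
    "select": 6,
    "fit": 7,
    "cluster": 8,
}


def derive_seed(master: int, stage: str, *indices: int) -> int:
    """Deterministic child seed for a pipeline stage.

    Children are drawn from ``np.random.SeedSequence(master,
    spawn_key=(stage_key, *indices))`` so per-contact work can run in any
    order (or concurrently) with results identical to serial execution.
    """
    ss = np.random.SeedSequence(master, spawn_key=(_STAGE_KEYS[stage], *indices))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Full pipeline configuration (synthetic or file-based input)."""

    mode: str = "synthetic"  # "synthetic" | "files"
    synth: SynthConfig | None = field(default_factory=SynthConfig)
    edf_path: str | None = None
    events_path: str | None = None
    electrodes_path: str | None = None
    tfr: TFRConfig = field(default_factory=TFRConfig)
    n_components: int = 50
    k_folds: int = 6
    alpha: float = 0.01
    C: float = 1.0
    null_n_obs: int | None = None  # default: presentations per modality
    cluster_alpha: float = 0.01
    n_perm: int = 1000
    iti_guard_s: float = 1.99
    formats: tuple[str, ...] = FORMATS
    run_cluster_tests: bool = True
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "synthetic":
            if self.synth is None:
                raise ValueError("synthetic mode requires a synth config")
            self.synth.validate()
        else:
            for p, name in [
                (self.edf_path, "edf_path"),
                (self.events_path, "events_path"),
                (self.electrodes_path, "electrodes_path"),
            ]:
                if not p or not Path(p).exists():
                    raise ValueError(f"files mode requires an existing {name}")
        unknown = set(self.formats) - set(FORMATS)
        if unknown:
            raise ValueError(f"unknown formats {sorted(unknown)}")
        if not (0 < self.alpha < 1) or not (0 < self.cluster_alpha < 1):
            raise ValueError("alpha values must lie in (0, 1)")
        if self.k_folds < 2 or self.n_components < 1 or self.n_perm < 1:
            raise ValueError("invalid classifier/cluster settings")

    def to_dict(self) -> dict:
        def _conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: _conv(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [_conv(v) for v in obj]
            return obj

        d = {k: _conv(v) for k, v in dataclasses.asdict(self).items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .synth import EffectSpec, NoiseModel

        d = dict(d)
        if d.get("synth") is not None:
            s = dict(d["synth"])
            s["effects"] = tuple(
                EffectSpec(
                    contact=e["contact"],
                    modalities=tuple(e["modalities"]),
                    band_hz=tuple(e["band_hz"]),
                    window_s=tuple(e["window_s"]),
                    direction=e.get("direction", "increase"),
                    magnitude=e.get("magnitude", 1.0),
                    erp_amplitude=e.get("erp_amplitude", 0.0),
                )
                for e in s.get("effects", [])
            )
            s["noise"] = NoiseModel(**s.get("noise", {}))
            cls_fields = {f.name for f in dataclasses.fields(SynthConfig)}
            d["synth"] = SynthConfig(**{k: v for k, v in s.items() if k in cls_fields})
        if d.get("tfr") is not None:
            t = dict(d["tfr"])
            t["freqs_hz"] = np.asarray(t["freqs_hz"], dtype=float)
            if t.get("n_cycles") is not None:
                t["n_cycles"] = np.asarray(t["n_cycles"], dtype=float)
            t["bandpass_hz"] = tuple(t["bandpass_hz"])
            d["tfr"] = TFRConfig(**t)
        d["formats"] = tuple(d.get("formats", FORMATS))
        cls_fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in cls_fields})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ResultsBundle:
    """Everything one pipeline run produced, plus provenance."""

    results: list[ContactDecoderResults]
    clusters: dict[tuple[str, str], ClusterSet]
    counts: dict[str, int]
    region_maps: dict[str, object]
    feature_map_bundles: dict[str, FeatureMapBundle]
    electrodes: pd.DataFrame
    provenance: dict
    n_epochs_kept: dict[str, int]

    def summary_frame(self) -> pd.DataFrame:
        region_of = dict(zip(self.electrodes["name"], self.electrodes["region"]))
        rows = [
            {
                "contact": r.contact,
                "region": region_of.get(r.contact, "unknown"),
                "format": r.format,
                "n_test": r.n_test,
                "n_correct": r.n_correct,
                "accuracy": r.accuracy,
                "p_value": r.p_value,
                "significant": int(r.significant),
            }
            for r in self.results
        ]
        df = pd.DataFrame(rows)
        return df.sort_values(["contact", "format"]).reset_index(drop=True)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(
            out / "summary.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pd.DataFrame(
            [{"format": k, "n_significant": v} for k, v in sorted(self.counts.items())]
        ).to_csv(out / "counts.tsv", sep="\t", index=False)
        region_rows = []
        for fmt, rmap in sorted(self.region_maps.items()):
            for region, (acc, n, ns) in sorted(rmap.entries.items()):
                region_rows.append(
                    {
                        "format": fmt,
                        "region": region,
                        "accuracy": acc,
                        "n_contacts": n,
                        "n_significant": ns,
                    }
                )
        pd.DataFrame(
            region_rows, columns=["format", "region", "accuracy", "n_contacts", "n_significant"]
        ).to_csv(out / "region_accuracy.tsv", sep="\t", index=False, float_format="%.10g")
        with h5py.File(out / "feature_maps.h5", "w") as f:
            for fmt, bundle in self.feature_map_bundles.items():
                g = f.create_group(fmt)
                g.create_dataset("proportion_significant", data=bundle.proportion_significant)
                g.create_dataset("proportion_positive", data=bundle.proportion_positive)
                g.create_dataset("classification_value", data=bundle.classification_value)
                g.attrs["n_contacts"] = bundle.n_contacts
        with h5py.File(out / "bundle.h5", "w") as f:
            for r in self.results:
                g = f.create_group(f"{r.contact}/{r.format}")
                g.attrs.update(
                    accuracy=r.accuracy,
                    p_value=r.p_value,
                    significant=bool(r.significant),
                    n_test=r.n_test,
                    n_correct=r.n_correct,
                    seed=r.seed,
                )
                for i, fold in enumerate(r.folds):
                    fg = g.create_group(f"fold{i}")
                    fg.create_dataset("components", data=fold.components)
                    fg.create_dataset("coef", data=fold.coef)
                    fg.attrs["intercept"] = fold.intercept
                    fg.create_dataset("feat_mean", data=fold.feat_mean)
                    fg.create_dataset("feat_sd", data=fold.feat_sd)
                    fg.create_dataset("pca_mean", data=fold.pca_mean)
                    fg.create_dataset("test_idx", data=fold.test_idx)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def _load_inputs(config: RunConfig):
    if config.mode == "synthetic":
        schedule = build_schedule(config.synth, derive_seed(config.seed, "schedule"))
        rec, manifest = simulate_recording(
            schedule, config.synth, derive_seed(config.seed, "recording")
        )
        if config.synth.region_labels is not None:
            electrodes = make_electrode_table(config.synth)
        else:
            electrodes = pd.DataFrame(
                {"name": rec.ch_names, "region": ["unknown"] * rec.n_channels}
            )
        return rec, schedule, electrodes, manifest
    rec = sio.read_edf(config.edf_path)
    schedule = sio.read_events_tsv(config.events_path)
    electrodes = sio.read_electrodes_tsv(config.electrodes_path)
    return rec, schedule, electrodes, None


def _format_selection(
    epochs: EpochSet, fmt: str, seed: int
) -> np.ndarray | None:
    """Balanced epoch indices (into the kept set) for one format contrast."""
    rng = np.random.default_rng(seed)
    stim = np.flatnonzero(
        (epochs.condition == STIMULUS)
        & (np.ones(epochs.n_epochs, bool) if fmt == "all" else epochs.modality == fmt)
    )
    iti = np.flatnonzero(epochs.condition == ITI)
    n = min(len(stim), len(iti))
    if n == 0:
        return None
    if len(stim) > n:
        stim = np.sort(rng.choice(stim, size=n, replace=False))
    if len(iti) > n:
        iti = np.sort(rng.choice(iti, size=n, replace=False))
    return np.concatenate([stim, iti])


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute every stage for every contact and format; returns the bundle
    (and writes it to ``config.out_dir`` when set)."""
    t0 = time.time()
    config.validate()
    rec, schedule, electrodes, manifest = _load_inputs(config)
    logger.info("recording: %d contacts, %.1f s", rec.n_channels, rec.duration_s)

    rec = average_reference(rec)
    epochs = extract_epochs(
        rec,
        schedule,
        iti_guard_s=config.iti_guard_s,
        balance=False,
        seed=derive_seed(config.seed, "epochs"),
    )
    threshold = estimate_rejection_threshold(
        epochs, seed=derive_seed(config.seed, "threshold")
    )
    epochs = drop_bad_epochs(
        epochs, threshold, seed=derive_seed(config.seed, "reject"), rebalance=False
    )
    kept = epochs.kept()
    counts_kept = kept.class_counts()
    logger.info(
        "epochs kept after rejection (threshold %.1f uV): %s", threshold, counts_kept
    )

    null = NullSpec(
        p0=0.5,
        n_obs=(
            config.null_n_obs
            if config.null_n_obs is not None
            else (config.synth.presentations_per_modality if config.synth else 40)
        ),
        alpha=config.alpha,
    )

    results: list[ContactDecoderResults] = []
    clusters: dict[tuple[str, str], ClusterSet] = {}
    for ci, contact in enumerate(rec.ch_names):
        selections: dict[str, np.ndarray] = {}
        for fi, fmt in enumerate(config.formats):
            sel = _format_selection(kept, fmt, derive_seed(config.seed, "select", ci, fi))
            if sel is None:
                logger.warning("no balanced epochs for %s/%s; skipped", contact, fmt)
                continue
            selections[fmt] = sel
        if not selections:
            continue
        union = np.unique(np.concatenate(list(selections.values())))
        sub = kept.select(union)
        power, times = morlet_power(sub, config.tfr, contact)
        voltage, _ = bandpass_voltage(sub, contact, cfg=config.tfr)
        feats_all = build_feature_matrix(
            power, voltage, config.tfr, times=times
        )
        pos_in_union = {int(e): i for i, e in enumerate(union)}
        for fi, fmt in enumerate(config.formats):
            if fmt not in selections:
                continue
            sel = selections[fmt]
            rows = np.array([pos_in_union[int(e)] for e in sel])
            feats = feats_all.select(rows)
            labels = kept.condition[sel]
            model = ContactDecoder(
                feats,
                labels,
                n_components=config.n_components,
                k_folds=config.k_folds,
                C=config.C,
                null=null,
                contact=contact,
                format=fmt,
            )
            res = model.fit(seed=derive_seed(config.seed, "fit", ci, fi))
            results.append(res)
            if res.significant and config.run_cluster_tests:
                clusters[(contact, fmt)] = res.cluster_test(
                    alpha=config.cluster_alpha,
                    n_perm=config.n_perm,
                    seed=derive_seed(config.seed, "cluster", ci, fi),
                )
    logger.info("fitted %d contact x format decoders", len(results))

    counts = count_significant(results)
    region_maps = {}
    fmb = {}
    for fmt in config.formats:
        fmt_results = [r for r in results if r.format == fmt]
        if not fmt_results:
            continue
        region_maps[fmt] = region_accuracy(fmt_results, electrodes)
        pairs = [(r, clusters.get((r.contact, fmt))) for r in fmt_results]
        if any(cs is not None for _, cs in pairs):
            fmb[fmt] = feature_maps(pairs, format=fmt)

    cfg_dict = RunConfig.to_dict(config)
    provenance = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __pkg_version__(),
        "rejection_threshold_uv": threshold,
        "epochs_kept": counts_kept,
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if manifest is not None:
        provenance["ground_truth_manifest"] = manifest

    bundle = ResultsBundle(
        results=results,
        clusters=clusters,
        counts=counts,
        region_maps=region_maps,
        feature_map_bundles=fmb,
        electrodes=electrodes,
        provenance=provenance,
        n_epochs_kept=counts_kept,
    )
    if config.out_dir:
        bundle.save(config.out_dir)
    return bundle


def __pkg_version__() -> str:
    from . import __version__

    return __version__
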