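"""End-to-end orchestration: simulate → preprocess → connectivity →
network metrics → group statistics, with provenance and region summaries.

``run_all`` drives the whole chain from one :class:`SimulationConfig`
plus :class:`PipelineSettings`, writes every intermediate as plain
CSV/TSV/JSON under the output directory, and returns a manifest with a
config hash, per-file checksums, and every warning-producing event
(artifact rejections, IAF fallbacks, baseline division floors). Given
the same (config, seed) the output bytes are identical run to run.

Stage functions (`preprocess_subject`, `connect_subject`, ...) are
importable on their own so the CLI can run stages separately against
files on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .connectivity import (
    ConnectivityMatrix,
    analytic_signal,
    channel_mean_wpli,
    erwpli,
    mean_wpli,
    wpli,
)
from .graph import NetworkMetrics, network_metrics
from .montage import DEFAULT_REGIONS
from .preprocess import (
    EpochTensor,
    IAFEstimate,
    RejectionReport,
    bandpass_fir,
    bandpass_fir_multi,
    bands_from_iaf,
    epoch,
    estimate_iaf,
    reject_artifacts,
)
from .simulate import SimulationConfig, SubjectData, simulate_cohort
from .stats import (
    correlate_with_performance,
    edgewise_compare,
    ks_normality,
    nodewise_compare,
    wilcoxon_ranksum,
)

GLOBAL_METRICS = ("mean_wpli", "avg_clustering", "char_path_length", "global_efficiency")
NODAL_METRICS = ("channel_mean_wpli", "local_efficiency", "eigenvector_centrality")


@dataclass(frozen=True)
class PipelineSettings:
    """Every stage default, spelled out so the analysis windows are visible."""

    full_window: tuple[float, float] = (-5.0, 2.0)
    aiming_window: tuple[float, float] = (-3.0, 0.0)
    baseline_window: tuple[float, float] = (-4.0, -3.0)
    broadband: tuple[float, float] = (0.1, 50.0)
    fir_order: int = 1000
    reject_uv: float = 150.0
    trim_fraction: float = 0.10
    wpli_average: str = "within_trial"
    erwpli_floor: float = 1e-6
    alpha: float = 0.05
    iaf_resolution: float = 0.5
    contrasts: tuple[tuple[str, str], ...] = (("noise", "control"), ("weak_light", "control"))
    paired: bool = False
    write_raw: bool = False
    # filtering precision; float32 halves FFT cost and is far below the
    # stochastic uncertainty of any trial-averaged connectivity estimate
    compute_dtype: str = "float32"


@dataclass
class RegionMap:
    """Named, non-overlapping scalp regions over the montage channels."""

    regions: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_REGIONS))

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, chans in self.regions.items():
            for ch in chans:
                if ch in seen:
                    raise ValueError(f"channel {ch!r} in both {seen[ch]!r} and {name!r}")
                seen[ch] = name

    def validate_against(self, channel_labels) -> None:
        unknown = [c for r in self.regions.values() for c in r if c not in channel_labels]
        if unknown:
            raise ValueError(f"region channels absent from the montage: {unknown}")

    def region_of(self, channel: str) -> str | None:
        for name, chans in self.regions.items():
            if channel in chans:
                return name
        return None


@dataclass
class PreprocessedSubject:
    subject_id: str
    iaf: IAFEstimate
    bands: tuple
    # (condition, band) -> (aiming epochs, baseline epochs)
    epochs: dict[tuple[str, str], tuple[EpochTensor, EpochTensor]]
    rejections: dict[str, RejectionReport]


@dataclass
class SubjectConnectivity:
    subject_id: str
    # (condition, band) -> {"aiming": ..., "baseline": ..., "erwpli": ...}
    matrices: dict[tuple[str, str], dict]
    n_floored: int = 0


def preprocess_subject(subject: SubjectData, settings: PipelineSettings) -> PreprocessedSubject:
    """IAF, band division, filtering, epoching and rejection for one subject.

    The broadband 0.1-50 Hz filter and each band filter are applied to
    the continuous signal; trials are then cut over the full -5..+2 s
    span, rejected once on the broadband data, and the aiming and
    baseline sub-windows are sliced from the retained trials so both
    share identical rejection.
    """
    iaf_est = estimate_iaf(subject.resting, resolution=settings.iaf_resolution)
    bands = bands_from_iaf(iaf_est)
    epochs: dict[tuple[str, str], tuple[EpochTensor, EpochTensor]] = {}
    rejections: dict[str, RejectionReport] = {}
    from .preprocess import replace_recording

    for cond, rec in subject.recordings.items():
        rec = replace_recording(rec, rec.samples.astype(settings.compute_dtype))
        broad = bandpass_fir(rec, *settings.broadband, order=settings.fir_order)
        full = epoch(broad, settings.full_window)
        _, report = reject_artifacts(full, settings.reject_uv)
        keep = np.setdiff1d(full.retained_trial_ids, np.asarray(report.removed_ids, dtype=np.int64))
        rejections[cond] = report
        band_recs = bandpass_fir_multi(broad, list(bands), order=settings.fir_order)
        for band in bands:
            band_rec = band_recs[band.name]
            band_full = epoch(band_rec, settings.full_window, event_ids=keep, band_label=band.name)
            aiming = band_full.subwindow(*settings.aiming_window)
            baseline = band_full.subwindow(*settings.baseline_window)
            epochs[(cond, band.name)] = (aiming, baseline)
    return PreprocessedSubject(
        subject_id=subject.subject_id,
        iaf=iaf_est,
        bands=bands,
        epochs=epochs,
        rejections=rejections,
    )


def connect_subject(pre: PreprocessedSubject, settings: PipelineSettings) -> SubjectConnectivity:
    """WPLI (aiming + baseline) and ERWPLI matrices for one subject."""
    matrices: dict[tuple[str, str], dict] = {}
    n_floored = 0
    for key, (aiming, baseline) in pre.epochs.items():
        w = wpli(analytic_signal(aiming, settings.trim_fraction), settings.wpli_average)
        r = wpli(analytic_signal(baseline, settings.trim_fraction), settings.wpli_average)
        e = erwpli(w, r, settings.erwpli_floor)
        n_floored += e.n_floored
        matrices[key] = {"aiming": w, "baseline": r, "erwpli": e}
    return SubjectConnectivity(subject_id=pre.subject_id, matrices=matrices, n_floored=n_floored)


def metrics_table(connectivity: list[SubjectConnectivity]) -> tuple[pd.DataFrame, dict]:
    """Tidy metric rows and the raw NetworkMetrics per (subject, cond, band)."""
    rows = []
    raw: dict[tuple[str, str, str], NetworkMetrics] = {}
    for sc in connectivity:
        for (cond, band), mats in sc.matrices.items():
            w: ConnectivityMatrix = mats["aiming"]
            m = network_metrics(w.values)
            raw[(sc.subject_id, cond, band)] = m
            common = {"subject_id": sc.subject_id, "condition": cond, "band": band}
            rows.append({**common, "metric": "mean_wpli", "node": "global", "value": mean_wpli(w)})
            rows.append({**common, "metric": "avg_clustering", "node": "global", "value": m.avg_clustering})
            rows.append({**common, "metric": "char_path_length", "node": "global", "value": m.char_path_length})
            rows.append({**common, "metric": "global_efficiency", "node": "global", "value": m.global_efficiency})
            cmw = channel_mean_wpli(w)
            for i, ch in enumerate(w.channel_labels):
                rows.append({**common, "metric": "channel_mean_wpli", "node": ch, "value": cmw[i]})
                rows.append({**common, "metric": "local_efficiency", "node": ch, "value": m.local_efficiency[i]})
                rows.append({**common, "metric": "eigenvector_centrality", "node": ch, "value": m.eigenvector_centrality[i]})
    return pd.DataFrame(rows), raw


def _stack(connectivity, cond, band, which="aiming"):
    return [sc.matrices[(cond, band)][which] for sc in connectivity]


def group_statistics(
    connectivity: list[SubjectConnectivity],
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    channel_labels,
    settings: PipelineSettings,
    bands=("theta", "alpha", "beta"),
) -> dict[str, pd.DataFrame]:
    """Edgewise / nodewise / global contrasts and performance correlations."""
    edge_rows, node_rows, global_rows, screen_rows, corr_rows = [], [], [], [], []
    for band in bands:
        for cond_a, cond_b in settings.contrasts:
            label = f"{cond_a}_vs_{cond_b}"
            a = _stack(connectivity, cond_a, band)
            b = _stack(connectivity, cond_b, band)
            edf = edgewise_compare(
                a, b, channel_labels, settings.alpha, label, settings.paired
            )
            edf.insert(0, "band", band)
            edge_rows.append(edf)
            va = np.array([channel_mean_wpli(m) for m in a])
            vb = np.array([channel_mean_wpli(m) for m in b])
            ndf = nodewise_compare(va, vb, channel_labels, settings.alpha, label, settings.paired)
            ndf.insert(0, "band", band)
            ndf.insert(1, "family", "channel_mean_wpli")
            node_rows.append(ndf)
            # nodal graph metrics
            for metric in ("local_efficiency", "eigenvector_centrality"):
                fa = _nodal_matrix(metrics, metric, cond_a, band, channel_labels)
                fb = _nodal_matrix(metrics, metric, cond_b, band, channel_labels)
                mdf = nodewise_compare(fa, fb, channel_labels, settings.alpha, label, settings.paired)
                mdf.insert(0, "band", band)
                mdf.insert(1, "family", metric)
                node_rows.append(mdf)
            # global metrics
            for metric in GLOBAL_METRICS:
                ga = _global_vector(metrics, metric, cond_a, band)
                gb = _global_vector(metrics, metric, cond_b, band)
                r = wilcoxon_ranksum(ga, gb)
                global_rows.append(
                    {
                        "band": band,
                        "contrast": label,
                        "metric": metric,
                        "statistic": r.statistic,
                        "p_raw": r.p_raw,
                        "mean_a": float(np.mean(ga)),
                        "mean_b": float(np.mean(gb)),
                    }
                )
                screen_rows.append(
                    {
                        "band": band,
                        "group": cond_a,
                        "metric": metric,
                        "ks_p": (
                            ks_normality(ga).p_raw
                            if len(ga) >= 4 and np.unique(ga).size > 1
                            else np.nan
                        ),
                    }
                )
        # performance correlations per condition, family = global metrics
        for cond in scores["condition"].unique():
            mean_scores = (
                scores[scores["condition"] == cond]
                .groupby("subject_id")["ring_score"]
                .mean()
                .sort_index()
            )
            if len(mean_scores) < 5:
                continue
            feats = {}
            for metric in GLOBAL_METRICS:
                feats[metric] = _global_series(metrics, metric, cond, band)
            fdf = pd.DataFrame(feats).sort_index()
            cdf = correlate_with_performance(fdf, mean_scores.loc[fdf.index], settings.alpha)
            cdf.insert(0, "band", band)
            cdf.insert(1, "condition", cond)
            cdf.insert(2, "family", "global_metrics")
            corr_rows.append(cdf)
    out = {
        "edgewise": pd.concat(edge_rows, ignore_index=True),
        "nodewise": pd.concat(node_rows, ignore_index=True),
        "global": pd.DataFrame(global_rows),
        "ks_screen": pd.DataFrame(screen_rows),
        "performance": (
            pd.concat(corr_rows, ignore_index=True)
            if corr_rows
            else pd.DataFrame(columns=["band", "condition", "family", "feature_id", "rho", "p_raw", "n", "p_adjusted", "significant"])
        ),
    }
    return out


def _nodal_matrix(metrics, metric, cond, band, channel_labels):
    sel = metrics[(metrics["metric"] == metric) & (metrics["condition"] == cond) & (metrics["band"] == band)]
    pivot = sel.pivot(index="subject_id", columns="node", values="value")
    return pivot[list(channel_labels)].sort_index().to_numpy()


def _global_vector(metrics, metric, cond, band):
    return _global_series(metrics, metric, cond, band).to_numpy()


def _global_series(metrics, metric, cond, band):
    sel = metrics[
        (metrics["metric"] == metric)
        & (metrics["condition"] == cond)
        & (metrics["band"] == band)
        & (metrics["node"] == "global")
    ]
    return sel.set_index("subject_id")["value"].sort_index()


def region_summary(nodal_results: pd.DataFrame, regions: RegionMap | None = None) -> pd.DataFrame:
    """Mean value / significance counts per scalp region.

    ``nodal_results`` needs a ``feature_id`` column of channel names and
    a boolean ``significant`` column (as produced by
    :func:`aimnet.stats.nodewise_compare`); a ``statistic`` column, if
    present, is averaged per region.
    """
    regions = regions or RegionMap()
    rows = []
    for name, chans in regions.regions.items():
        sel = nodal_results[nodal_results["feature_id"].isin(chans)]
        rows.append(
            {
                "region": name,
                "n_channels": len(chans),
                "n_tested": len(sel),
                "n_significant": int(sel["significant"].sum()) if len(sel) else 0,
                "mean_statistic": float(sel["statistic"].mean()) if "statistic" in sel and len(sel) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _config_hash(config: SimulationConfig, settings: PipelineSettings) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o).__name__)

    payload = json.dumps(
        {"config": dataclasses.asdict(config), "settings": dataclasses.asdict(settings)},
        sort_keys=True,
        default=default,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_all(
    config: SimulationConfig,
    out_dir,
    settings: PipelineSettings | None = None,
    seed: int | None = None,
) -> dict:
    """Run every stage end-to-end; returns the run manifest (also written).

    Outputs under ``out_dir``: ``connectivity/`` (square CSV per subject
    x condition x band x {aiming, baseline, erwpli}), ``network/metrics.csv``,
    ``stats/*.csv``, ``region_summary.csv``, ``manifest.json``, and the
    raw cohort if ``settings.write_raw``.
    """
    settings = settings or PipelineSettings()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[dict] = []

    subjects, truth = simulate_cohort(config, out_dir / "raw" if settings.write_raw else None)

    pre = []
    for s in subjects:
        p = preprocess_subject(s, settings)
        pre.append(p)
        if p.iaf.is_fallback:
            warnings_log.append({"stage": "preprocess", "subject": s.subject_id, "event": "iaf_fallback"})
        for cond, rep in p.rejections.items():
            if rep.removed_ids:
                warnings_log.append(
                    {
                        "stage": "preprocess",
                        "subject": s.subject_id,
                        "condition": cond,
                        "event": "trials_rejected",
                        "removed": rep.removed_ids,
                        "rate": rep.removal_rate,
                    }
                )

    written: list[Path] = []
    conn = []
    for p in pre:
        sc = connect_subject(p, settings)
        conn.append(sc)
        if sc.n_floored:
            warnings_log.append(
                {"stage": "connectivity", "subject": sc.subject_id, "event": "erwpli_floor", "count": sc.n_floored}
            )
        for (cond, band), mats in sc.matrices.items():
            for which, m in mats.items():
                written.append(
                    io.write_matrix(m, out_dir / "connectivity" / f"{sc.subject_id}_{cond}_{band}_{which}.csv")
                )

    metrics, _ = metrics_table(conn)
    metrics_path = out_dir / "network" / "metrics.csv"
    metrics_path.parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(metrics_path, index=False, float_format="%.8f")
    written.append(metrics_path)

    scores = pd.DataFrame(
        [
            {"subject_id": s.subject_id, "condition": c, "ring_score": v}
            for s in subjects
            for c, rec in s.performance.items()
            for v in rec.ring_scores
        ]
    )
    scores_path = out_dir / "scores.csv"
    scores.to_csv(scores_path, index=False)
    written.append(scores_path)

    results = group_statistics(conn, metrics, scores, config.channel_labels, settings)
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        path = stats_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.8g")
        written.append(path)

    regions = RegionMap()
    regions.validate_against(config.channel_labels)
    region_rows = []
    node_df = results["nodewise"]
    for (band, family, contrast), grp in node_df.groupby(["band", "family", "contrast"]):
        rdf = region_summary(grp, regions)
        rdf.insert(0, "band", band)
        rdf.insert(1, "family", family)
        rdf.insert(2, "contrast", contrast)
        region_rows.append(rdf)
    region_path = out_dir / "region_summary.csv"
    pd.concat(region_rows, ignore_index=True).to_csv(region_path, index=False, float_format="%.8g")
    written.append(region_path)

    summary = {
        "significant_edges": {
            f"{band}|{contrast}": int(grp["significant"].sum())
            for (band, contrast), grp in results["edgewise"].groupby(["band", "contrast"])
        },
        "significant_nodes": {
            f"{band}|{family}|{contrast}": int(grp["significant"].sum())
            for (band, family, contrast), grp in results["nodewise"].groupby(["band", "family", "contrast"])
        },
    }

    manifest = {
        "config_hash": _config_hash(config, settings),
        "seed": config.seed,
        "package": "aimnet 0.1.0",
        "iaf_by_subject": {p.subject_id: p.iaf.iaf for p in pre},
        "summary": summary,
        "warnings": warnings_log,
        "outputs": {str(p.relative_to(out_dir)): io.sha256_of(p) for p in sorted(written)},
        "ground_truth": truth,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
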