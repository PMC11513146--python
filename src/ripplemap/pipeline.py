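"""End-to-end orchestration: SWS -> ripples -> assemblies -> memory
classification -> ripple taxonomy -> GLM decoding -> spatial maps.

``run_pipeline`` is deterministic given the config, writes one CSV/JSON per
stage plus a manifest, and skips stages whose inputs are absent (logged).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assemblies import (
    activation_strength,
    bin_and_zscore,
    count_significant_components,
    extract_assembly_patterns,
)
from .core import SessionBundle
from .decoding import (
    WindowSchedule,
    decode_and_score,
    rank_units_by_target_correlation,
    weight_split_decoding,
)
from .memory import (
    MemoryIndices,
    classify_memory_units,
    compute_mai,
    compute_rmi,
    is_ripple_modulated,
    peak_after_onset,
    peri_event_histogram,
    permutation_test_proportion,
)
from .ripples import detect_ripples_in_epoch, detect_sws
from .spatial import build_rate_map, compare_subgroups, place_cell_filter, spatial_information
from .taxonomy import (
    classify_ripples,
    compare_ripple_properties,
    firing_difference_scores,
    selectivity_index,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the published constants."""

    bin_ms: float = 25.0
    ripple_peak_sd: float = 5.0
    ripple_boundary_sd: float = 1.0
    ripple_min_duration_ms: float = 20.0
    envelope_smooth_sd_ms: float = 4.0
    trigger_sd: float = 8.0
    peh_window_ms: float = 500.0
    peh_bin_ms: float = 5.0
    peh_smooth_sd_ms: float = 15.0
    modulation_z: float = 3.3
    modulation_consecutive_bins: int = 3
    modulation_window_ms: float = 150.0
    member_sd: float = 2.0
    activation_sd: float = 5.0
    activation_mode: str = "quadratic"
    n_surrogates: int = 500
    n_shuffles: int = 100
    rmi_threshold: float = 1.0
    mai_threshold: float = 2.0
    memory_ripple_sd: float = 2.0
    lag_ms: float = 35.0
    glm_alpha: float = 1e-4
    place_bin_cm: float = 1.0
    place_smooth_bins: float = 5.0
    place_peak_hz: float = 0.4
    arena_cm: tuple[float, float] = (50.0, 50.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if "arena_cm" in known:
            cfg.arena_cm = tuple(cfg.arena_cm)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return int.from_bytes(
            hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()[:4], "little"
        )


@dataclass
class PipelineResult:
    ripples: dict = field(default_factory=dict)  # epoch -> list[RippleEvent]
    sws: dict = field(default_factory=dict)  # epoch -> intervals
    patterns: list = field(default_factory=list)
    traces: dict = field(default_factory=dict)  # epoch -> list[ActivationTrace]
    memory_table: list = field(default_factory=list)  # list[MemoryIndices]
    memory_assembly_id: Optional[int] = None
    permutation: Optional[object] = None
    labeled_ripples: list = field(default_factory=list)
    ripple_comparison: Optional[object] = None
    content_scores: list = field(default_factory=list)
    selectivity: dict = field(default_factory=dict)
    decoding: dict = field(default_factory=dict)
    spatial_table: Optional[pd.DataFrame] = None
    spatial_comparison: Optional[object] = None
    manifest: dict = field(default_factory=dict)


def _ripple_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "onset_s": r.onset_s,
                "peak_s": r.peak_s,
                "offset_s": r.offset_s,
                "amplitude_sd": r.amplitude_sd,
                "duration_ms": r.duration_ms,
                "label": r.label,
            }
            for r in events
        ]
    )


def run_pipeline(
    bundle: SessionBundle, cfg: RunConfig, out_dir: Optional[str | Path] = None
) -> PipelineResult:
    res = PipelineResult()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    # --- ripples + SWS per sleep epoch -------------------------------------
    if bundle.lfp is None:
        log.warning("no LFP in bundle; skipping ripple stages")
    else:
        for name in ("pre_sleep", "post_sleep"):
            if not bundle.has_epoch(name):
                log.warning("no %s epoch; skipping its ripple detection", name)
                continue
            epoch = bundle.epoch(name)
            first_pass = detect_ripples_in_epoch(
                bundle.lfp,
                epoch,
                peak_threshold_sd=cfg.ripple_peak_sd,
                boundary_sd=cfg.ripple_boundary_sd,
                min_duration_ms=cfg.ripple_min_duration_ms,
            )
            sws = detect_sws(
                bundle.lfp.slice(epoch.start_s, epoch.end_s), first_pass
            )
            events = detect_ripples_in_epoch(
                bundle.lfp,
                epoch,
                peak_threshold_sd=cfg.ripple_peak_sd,
                boundary_sd=cfg.ripple_boundary_sd,
                min_duration_ms=cfg.ripple_min_duration_ms,
                sws_intervals=sws,
            )
            res.ripples[name] = events
            res.sws[name] = sws
            counts[f"ripples_{name}"] = len(events)
            if out is not None:
                _ripple_frame(events).to_csv(out / f"ripples_{name}.csv", index=False)
                (out / f"sws_{name}.json").write_text(json.dumps(sws))

    # --- assemblies from post-training sleep --------------------------------
    bla = bundle.spikes.region("BLA")
    if not bundle.has_epoch("post_sleep") or bla.n_units == 0:
        log.warning("no post_sleep epoch or no BLA units; skipping assemblies")
        _write_manifest(res, cfg, counts, out)
        return res
    post = bundle.epoch("post_sleep")
    mat_post = bin_and_zscore(bla, post, bin_ms=cfg.bin_ms)
    n_sig = count_significant_components(mat_post)
    counts["significant_components"] = n_sig
    if n_sig < 1:
        log.warning("no significant co-activation components; stopping")
        _write_manifest(res, cfg, counts, out)
        return res
    patterns = extract_assembly_patterns(
        mat_post, n_sig, seed=cfg.stage_seed("ica")
    )
    for p in patterns:
        p.member_sd = cfg.member_sd
    res.patterns = patterns
    counts["assemblies"] = len(patterns)
    if out is not None:
        rows = []
        for p in patterns:
            for uid, w in zip(p.unit_ids, p.weights):
                rows.append(
                    {
                        "assembly_id": p.id,
                        "unit_id": int(uid),
                        "weight": float(w),
                        "is_member": bool(uid in p.members),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "assembly_patterns.csv", index=False)

    traces = {"post_sleep": [
        activation_strength(p, mat_post, mode=cfg.activation_mode,
                            threshold_sd=cfg.activation_sd)
        for p in patterns
    ]}
    if bundle.has_epoch("pre_sleep"):
        mat_pre = bin_and_zscore(bla, bundle.epoch("pre_sleep"), bin_ms=cfg.bin_ms)
        if np.array_equal(mat_pre.unit_ids, mat_post.unit_ids):
            traces["pre_sleep"] = [
                activation_strength(p, mat_pre, mode=cfg.activation_mode,
                                    threshold_sd=cfg.activation_sd)
                for p in patterns
            ]
        else:
            log.warning("unit sets differ across sleep epochs; no pre-sleep traces")
    res.traces = traces

    # --- memory classification ---------------------------------------------
    pre_rip = res.ripples.get("pre_sleep", [])
    post_rip = res.ripples.get("post_sleep", [])
    training = bundle.epoch("training") if bundle.has_epoch("training") else None
    peh_kw = dict(
        window_ms=cfg.peh_window_ms,
        bin_ms=cfg.peh_bin_ms,
        smooth_sd_ms=cfg.peh_smooth_sd_ms,
    )
    mod_kw = dict(
        z_threshold=cfg.modulation_z,
        n_consecutive=cfg.modulation_consecutive_bins,
        test_window_ms=cfg.modulation_window_ms,
    )
    if pre_rip and post_rip and "pre_sleep" in traces:
        pre_onsets = np.array([r.onset_s for r in pre_rip])
        post_onsets = np.array([r.onset_s for r in post_rip])
        indices = []
        for k, p in enumerate(patterns):
            ev_pre = traces["pre_sleep"][k].event_times
            ev_post = traces["post_sleep"][k].event_times
            peh_pre = peri_event_histogram(ev_pre, pre_onsets, **peh_kw)
            peh_post = peri_event_histogram(ev_post, post_onsets, **peh_kw)
            dur = (
                bundle.epoch("pre_sleep").duration_s
                + bundle.epoch("post_sleep").duration_s
            )
            baseline = (ev_pre.size + ev_post.size) / dur
            rmi = compute_rmi(peh_pre, peh_post, baseline, cfg.modulation_window_ms)
            mai = None
            if training is not None and bundle.shock_times.size:
                member_spikes = np.sort(
                    np.concatenate([bla.times[u] for u in sorted(p.members)])
                    if p.members
                    else np.array([])
                )
                mai = compute_mai(
                    member_spikes, bundle.shock_times, training.start_s, training.end_s
                )
            elif training is None or not bundle.shock_times.size:
                log.warning("no shocks/training epoch: MAI undefined for assembly %d", p.id)
            indices.append(
                MemoryIndices(
                    id=p.id,
                    rmi=rmi,
                    mai=mai,
                    pre_modulation=is_ripple_modulated(peh_pre, **mod_kw),
                    post_modulation=is_ripple_modulated(peh_post, **mod_kw),
                    baseline_hz=baseline,
                    peak_pre_hz=peak_after_onset(peh_pre, cfg.modulation_window_ms),
                    peak_post_hz=peak_after_onset(peh_post, cfg.modulation_window_ms),
                )
            )
        res.memory_table = classify_memory_units(
            indices, cfg.rmi_threshold, cfg.mai_threshold
        )
        memory_ids = [ix.id for ix in res.memory_table if ix.is_memory]
        counts["memory_assemblies"] = len(memory_ids)
        if memory_ids:
            res.memory_assembly_id = memory_ids[0]
        if res.sws.get("post_sleep"):
            res.permutation = permutation_test_proportion(
                [traces["post_sleep"][k].event_times for k in range(len(patterns))],
                post_onsets,
                res.sws["post_sleep"],
                n_shuffles=cfg.n_shuffles,
                seed=cfg.stage_seed("permutation"),
                **peh_kw,
            )
            counts["permutation_p"] = res.permutation.p_value
        if out is not None:
            pd.DataFrame(
                [
                    {
                        "assembly_id": ix.id,
                        "peak_pre_hz": ix.peak_pre_hz,
                        "peak_post_hz": ix.peak_post_hz,
                        "baseline_hz": ix.baseline_hz,
                        "rmi": ix.rmi,
                        "mai": ix.mai,
                        "pre_mod": ix.pre_modulation.direction,
                        "post_mod": ix.post_modulation.direction,
                        "label": "memory" if ix.is_memory else "non_memory",
                    }
                    for ix in res.memory_table
                ]
            ).to_csv(out / "memory_table.csv", index=False)
    else:
        log.warning("missing pre/post ripples or traces; memory classification skipped")

    # --- ripple taxonomy ----------------------------------------------------
    dca1 = bundle.spikes.region("dCA1")
    if res.memory_assembly_id is not None and post_rip:
        k = next(i for i, p in enumerate(patterns) if p.id == res.memory_assembly_id)
        res.labeled_ripples = classify_ripples(
            post_rip,
            traces["post_sleep"][k],
            window_ms=cfg.modulation_window_ms,
            threshold_sd=cfg.memory_ripple_sd,
        )
        counts["memory_ripples"] = sum(
            1 for r in res.labeled_ripples if r.label == "memory"
        )
        res.ripple_comparison = compare_ripple_properties(res.labeled_ripples)
        n_mem = counts["memory_ripples"]
        n_non = len(res.labeled_ripples) - n_mem
        if n_mem >= 2 and n_non >= 2 and dca1.n_units:
            res.content_scores = firing_difference_scores(
                dca1, res.labeled_ripples, split_seed=cfg.stage_seed("split")
            )
            res.selectivity = {
                sd: selectivity_index(res.labeled_ripples, sd) for sd in (4.0, 6.0, 8.0)
            }
        if out is not None:
            _ripple_frame(res.labeled_ripples).to_csv(
                out / "ripples_labeled.csv", index=False
            )
            if res.content_scores:
                pd.DataFrame(
                    [
                        {
                            "unit_id": s.unit_id,
                            "m_hz": s.m_hz,
                            "n_hz": s.n_hz,
                            "m_n": s.m_n,
                            "m1_m2": s.m1_m2,
                            "n1_n2": s.n1_n2,
                            "group": s.group,
                        }
                        for s in res.content_scores
                    ]
                ).to_csv(out / "content_scores.csv", index=False)
    else:
        log.warning("no memory assembly; ripple taxonomy skipped")

    # --- GLM decoding -------------------------------------------------------
    if res.memory_assembly_id is not None and dca1.n_units:
        k = next(i for i, p in enumerate(patterns) if p.id == res.memory_assembly_id)
        schedule = WindowSchedule(lag_ms=cfg.lag_ms)
        for name, rip in (("pre_sleep", pre_rip), ("post_sleep", post_rip)):
            if len(rip) < 20 or name not in traces:
                continue
            onsets = np.array([r.onset_s for r in rip])
            target = traces[name][k].event_times
            try:
                res.decoding[name] = decode_and_score(
                    dca1,
                    target,
                    onsets,
                    schedule=schedule,
                    split_seed=cfg.stage_seed(f"decode_{name}"),
                    n_shuffles=cfg.n_shuffles,
                    alpha=cfg.glm_alpha,
                )
            except ValueError as err:
                log.warning("decoding (%s) skipped: %s", name, err)
        if post_rip and "post_sleep" in traces and len(post_rip) >= 20:
            res.decoding["weight_split"] = weight_split_decoding(
                dca1,
                traces["post_sleep"][k].event_times,
                np.array([r.onset_s for r in post_rip]),
                schedule=schedule,
                split_seed=cfg.stage_seed("weight_split"),
                n_shuffles=cfg.n_shuffles,
                alpha=cfg.glm_alpha,
            )
        if out is not None and res.decoding:
            blob = {}
            for name, d in res.decoding.items():
                if isinstance(d, dict):
                    blob[name] = {
                        half: {"r": dd.r, "null_975": dd.null_percentile()}
                        for half, dd in d.items()
                    }
                else:
                    blob[name] = {"r": d.r, "null_975": d.null_percentile()}
            (out / "decoding.json").write_text(json.dumps(blob, indent=2))

    # --- spatial ------------------------------------------------------------
    if bundle.position is not None and dca1.n_units:
        maps = {}
        for uid in dca1.unit_ids("dCA1"):
            try:
                maps[uid] = build_rate_map(
                    dca1.times[uid],
                    bundle.position,
                    arena_cm=cfg.arena_cm,
                    bin_cm=cfg.place_bin_cm,
                    smooth_width_bins=cfg.place_smooth_bins,
                )
            except ValueError as err:
                log.warning("rate map for unit %d failed: %s", uid, err)
        included = set(place_cell_filter(maps, cfg.place_peak_hz))
        table = pd.DataFrame(
            [
                {
                    "unit_id": uid,
                    "peak_hz": m.peak_rate_hz,
                    "si_bits_per_spike": spatial_information(m),
                    "included": uid in included,
                }
                for uid, m in maps.items()
            ]
        )
        res.spatial_table = table
        counts["place_cells"] = len(included)
        if res.memory_assembly_id is not None and "post_sleep" in traces:
            k = next(i for i, p in enumerate(patterns) if p.id == res.memory_assembly_id)
            order = rank_units_by_target_correlation(
                dca1, traces["post_sleep"][k].event_times
            )
            half = len(order) // 2
            si = dict(zip(table.unit_id, table.si_bits_per_spike))
            inc = included
            res.spatial_comparison = compare_subgroups(
                [si[u] for u in order[:half] if u in inc],
                [si[u] for u in order[half:] if u in inc],
            )
        if out is not None:
            table.to_csv(out / "spatial.csv", index=False)
    else:
        log.warning("no position data; spatial stage skipped")

    _write_manifest(res, cfg, counts, out)
    return res


def _write_manifest(res: PipelineResult, cfg: RunConfig, counts: dict, out) -> None:
    res.manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "counts": counts,
    }
    if out is not None:
        (Path(out) / "manifest.json").write_text(
            json.dumps(res.manifest, indent=2, default=str)
        )
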