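"""End-to-end pipeline: sessions (real or simulated) -> report tables.

Per session: gaze reconstruction, AOI labels, trial-restricted coordination
slopes (yaw, pitch) and full-scenario entropies (eye, head, gaze). At the
cohort level: slope summary, entropy table, KS / ANOVA / Tukey report, and
a run manifest. Deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coordination import group_average_slopes, session_slopes
from .entropy import DisplacementThreshold, session_entropy
from .io import PipelineConfig, load_geometry, read_session
from .kinematics import SceneGeometry, assign_aoi, reconstruct_gaze
from .simulate import CohortSpec, simulate_cohort
from .stats import anova_condition_group, boxcox_if_skewed, ks_two_sample, tukey_hsd
from .traces import Session

log = logging.getLogger("gazescan")


def analyze_session(session: Session, config: PipelineConfig, geometry: SceneGeometry):
    """Slopes and entropies for one session; returns (slope rows, entropy rows)."""
    gaze = reconstruct_gaze(session.eye, session.head, config.reconstruct_mode)
    session.gaze = gaze
    aoi = assign_aoi(gaze, geometry)
    policy = DisplacementThreshold(config.entropy_theta_deg)
    slope_rows = [
        {
            "participant": r.participant,
            "condition": r.condition,
            "group": r.group,
            "axis": r.axis,
            "slope": r.slope,
            "intercept": r.intercept,
            "n_retained": r.n_retained,
            "n_total": r.n_total,
        }
        for r in session_slopes(
            session, bin_deg=config.density_bin_deg, min_count=config.density_min_count
        )
    ]
    entropy_rows = []
    for effector in ("eye", "head", "gaze"):
        res = session_entropy(
            session,
            effector,
            policy=policy,
            mode=config.entropy_mode,
            bin_ms=config.bin_ms,
            reconstruct_mode=config.reconstruct_mode,
        )
        entropy_rows.append(
            {
                "participant": session.participant,
                "condition": session.condition,
                "group": session.group,
                "effector": effector,
                "raw_bits": res.raw_bits,
                "normalized": res.normalized,
                "n_bins": res.n_bins,
                "policy": res.policy,
                "mode": res.mode,
            }
        )
    log.info(
        "session %s/%s: %d samples, aoi device share %.3f",
        session.participant,
        session.condition,
        len(session.eye),
        float(np.mean(aoi == "device")),
    )
    return slope_rows, entropy_rows


def _stats_report(
    slopes: pd.DataFrame, entropies: pd.DataFrame, sessions: Sequence[Session],
    config: PipelineConfig,
) -> dict:
    """KS tables on pooled rotations, ANOVA per outcome, Tukey tables."""
    ks_rows = []
    for effector in ("eye", "head", "gaze"):
        for axis in ("yaw", "pitch"):
            pools = {}
            for cond in ("optimal", "degraded"):
                vals = []
                for s in sessions:
                    if s.condition != cond:
                        continue
                    trace = {"eye": s.eye, "head": s.head, "gaze": s.gaze}[effector]
                    if trace is None:
                        continue
                    vals.append(getattr(trace, axis)[trace.valid])
                if vals:
                    pools[cond] = np.concatenate(vals)
            if len(pools) == 2:
                ks = ks_two_sample(pools["optimal"], pools["degraded"])
                ks_rows.append(
                    {
                        "effector": effector,
                        "axis": axis,
                        "D": ks.statistic,
                        "p": ks.p_value,
                        "n_optimal": ks.n_a,
                        "n_degraded": ks.n_b,
                    }
                )
    anova_tables, tukey_tables = {}, {}
    outcomes = {}
    for axis in ("yaw", "pitch"):
        sub = slopes[slopes["axis"] == axis]
        outcomes[f"slope_{axis}"] = sub.rename(columns={"slope": "value"})[
            ["participant", "condition", "group", "value"]
        ]
    for effector in ("eye", "head", "gaze"):
        sub = entropies[entropies["effector"] == effector]
        outcomes[f"entropy_{effector}"] = sub.rename(columns={"normalized": "value"})[
            ["participant", "condition", "group", "value"]
        ]
    transforms = {}
    for name, table in outcomes.items():
        values, record = boxcox_if_skewed(table["value"].to_numpy())
        table = table.assign(value=values)
        if record is not None:
            transforms[name] = asdict(record)
        res = anova_condition_group(table, mode=config.stats_mode)
        anova_tables[name] = res.table
        tukey_tables[name] = tukey_hsd(table)
    return {
        "ks": pd.DataFrame(ks_rows),
        "anova": anova_tables,
        "tukey": tukey_tables,
        "transforms": transforms,
    }


def run_pipeline(config: PipelineConfig):
    """Run the full analysis; writes the report bundle and returns it.

    Sessions come either from ``config.session_paths`` or, if none are
    given, from a simulated cohort per ``config.simulate`` (seeded by
    ``config.seed``). A failing session is skipped with a logged reason;
    the run aborts if more than 20% of sessions fail.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = (
        load_geometry(config.geometry_path)
        if config.geometry_path
        else SceneGeometry.default()
    )

    truth = None
    if config.session_paths:
        sessions = [read_session(p) for p in config.session_paths]
    else:
        spec_kwargs = dict(config.simulate or {})
        spec_kwargs.setdefault("master_seed", config.seed)
        if "n_per_group" in spec_kwargs:
            spec_kwargs["n_per_group"] = dict(spec_kwargs["n_per_group"])
        offsets = spec_kwargs.pop("param_offsets", None)
        spec = CohortSpec(**spec_kwargs)
        if offsets:
            spec.param_offsets = {
                tuple(k.split("/")) if isinstance(k, str) else tuple(k): v
                for k, v in offsets.items()
            }
        sessions, truth = simulate_cohort(spec)

    slope_rows, entropy_rows, failures = [], [], []
    analyzed = []
    for session in sessions:
        try:
            srows, erows = analyze_session(session, config, geometry)
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            log.warning("skipping session %s/%s: %s", session.participant,
                        session.condition, exc)
            failures.append((session.participant, session.condition, str(exc)))
            continue
        slope_rows.extend(srows)
        entropy_rows.extend(erows)
        analyzed.append(session)
    if len(failures) > 0.2 * len(sessions):
        raise RuntimeError(f"more than 20% of sessions failed: {failures}")

    slopes = pd.DataFrame(slope_rows)
    entropies = pd.DataFrame(entropy_rows)
    from .coordination import RegressionResult

    slope_summary = group_average_slopes(
        [
            RegressionResult(
                axis=r["axis"], slope=r["slope"], intercept=r["intercept"],
                n_retained=r["n_retained"], n_total=r["n_total"],
                participant=r["participant"], condition=r["condition"], group=r["group"],
            )
            for r in slope_rows
        ]
    )
    report = _stats_report(slopes, entropies, analyzed, config)

    slopes.to_csv(out_dir / "slopes.csv", index=False)
    slope_summary.to_csv(out_dir / "slope_summary.csv", index=False)
    entropies.to_csv(out_dir / "entropy.csv", index=False)
    report["ks"].to_csv(out_dir / "ks.csv", index=False)
    for name, tab in report["anova"].items():
        tab.to_csv(out_dir / f"anova_{name}.csv", index=False)
    for name, tab in report["tukey"].items():
        tab.to_csv(out_dir / f"tukey_{name}.csv", index=False)
    if truth is not None:
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_sessions": len(sessions),
        "n_failed": len(failures),
        "failures": failures,
        "transforms": report["transforms"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "slopes": slopes,
        "slope_summary": slope_summary,
        "entropies": entropies,
        "ks": report["ks"],
        "anova": report["anova"],
        "tukey": report["tukey"],
        "manifest": manifest,
        "sessions": analyzed,
    }
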