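"""Config-driven pipeline runner: simulate -> detect -> match -> allocate -> permtest.

The configuration is a mapping (usually loaded from YAML) with a block
per stage; unknown top-level keys or unknown keys inside a block are
rejected before anything runs. Every run writes a machine-readable
``manifest.json`` beside its outputs recording the resolved parameters,
the seed and a SHA-256 digest of every output file, so two runs with the
same config can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import allocation as alloc
from . import permutation as perm
from .errors import InvalidConfigError
from .events import CalciumEventDetector, TraceQC, event_rate
from .matching import FootprintMatcher
from .session import read_session, write_pair
from .simulate import SimConfig, generate_session_pair

__all__ = ["run_pipeline", "load_config"]

log = logging.getLogger("miniens")

_STAGES = ("simulate", "detect", "match", "allocate", "permtest")
_TOP_KEYS = set(_STAGES) | {"seed", "outdir", "input", "verbosity"}

_STAGE_KEYS = {
    "simulate": {f.name for f in dataclasses.fields(SimConfig)},
    "detect": {
        "kernel_sds_ms",
        "decim_factor",
        "iqr_multiplier",
        "fps",
        "decim_mode",
        "merge_consecutive",
        "qc_pnr_min",
        "qc_asymmetry_max",
        "apply_qc",
    },
    "match": {"corr_min", "dist_max_px", "alignment_mode"},
    "allocate": {"q", "q_b"},
    "permtest": {"n_shuffles", "q", "exclude_triple", "plus_one_correction"},
}


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidConfigError("pipeline config must be a mapping")
    return cfg


def _validate(cfg: dict) -> None:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    for stage, keys in _STAGE_KEYS.items():
        block = cfg.get(stage)
        if block is None:
            continue
        if not isinstance(block, dict):
            raise InvalidConfigError(f"stage block '{stage}' must be a mapping")
        bad = set(block) - keys
        if bad:
            raise InvalidConfigError(f"unknown keys in '{stage}': {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(".tmp")
    df.to_csv(tmp, index=False, lineterminator="\n")
    tmp.replace(path)


def run_pipeline(cfg: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages in order; return a result bundle.

    Stages present in the config run in the fixed order simulate,
    detect, match, allocate, permtest; later stages consume the outputs
    of earlier ones (or, for a detect-only run, the session under
    ``input``). Outputs are delimited text plus the session containers;
    ``manifest.json`` lists parameters and output digests.
    """
    _validate(cfg)
    outdir = Path(outdir if outdir is not None else cfg.get("outdir", "miniens_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    verbosity = int(cfg.get("verbosity", 1))
    logging.basicConfig(
        stream=sys.stderr,
        level={0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG),
        format="%(name)s %(levelname)s %(message)s",
    )
    bundle: dict = {"outdir": str(outdir)}
    outputs: list[Path] = []
    sessions = []

    if "simulate" in cfg:
        sim_cfg = SimConfig(**{**cfg["simulate"], "seed": seed})
        log.info("simulate: %d neurons, %.0f s", sim_cfg.n_neurons, sim_cfg.duration_s)
        s1, s2, gt = generate_session_pair(sim_cfg)
        write_pair(s1, s2, gt, outdir / "sessions")
        for sub in ("session1", "session2"):
            for f in sorted((outdir / "sessions" / sub).iterdir()):
                outputs.append(f)
        if (outdir / "sessions" / "ground_truth.json").exists():
            outputs.append(outdir / "sessions" / "ground_truth.json")
        sessions = [s1, s2]
        bundle["ground_truth"] = gt
    elif "input" in cfg:
        inp = Path(cfg["input"])
        if (inp / "meta.json").exists():
            sessions = [read_session(inp)]
        else:
            sessions = [read_session(inp / "session1"), read_session(inp / "session2")]

    rate_tables = []
    keep_masks = []
    if "detect" in cfg:
        if not sessions:
            raise InvalidConfigError("detect stage requires simulate or input")
        blk = dict(cfg["detect"])
        apply_qc = blk.pop("apply_qc", True)
        pnr_min = blk.pop("qc_pnr_min", 20.0)
        asym_max = blk.pop("qc_asymmetry_max", 2.0)
        for s in sessions:
            det = CalciumEventDetector(fps=s.fps, **blk)
            raster = det.fit(s.traces).transform(s.traces)
            rates = event_rate(raster, session_id=s.session_id)
            qc = TraceQC(pnr_min, asym_max, fps=s.fps).fit(s.traces)
            rates["qc_keep"] = qc.report_["keep"]
            if apply_qc:
                rates.loc[~rates["qc_keep"], ["rate_per_point", "rate_events_per_s"]] = np.nan
            _write_csv(rates, outdir / f"rates_{s.session_id}.csv")
            _write_csv(qc.report_, outdir / f"qc_{s.session_id}.csv")
            ev = pd.DataFrame(raster.events)
            ev.insert(0, "neuron", np.arange(raster.n_neurons))
            _write_csv(ev, outdir / f"events_{s.session_id}.csv")
            outputs += [
                outdir / f"rates_{s.session_id}.csv",
                outdir / f"qc_{s.session_id}.csv",
                outdir / f"events_{s.session_id}.csv",
            ]
            rate_tables.append(rates)
            keep_masks.append(qc.report_["keep"].to_numpy())
            log.info(
                "detect %s: %d neurons, %d kept by QC",
                s.session_id,
                len(rates),
                int(rates["qc_keep"].sum()),
            )
        bundle["rates"] = rate_tables

    match_result = None
    if "match" in cfg:
        if len(sessions) < 2:
            raise InvalidConfigError("match stage requires two sessions")
        matcher = FootprintMatcher(**cfg["match"]).fit(
            sessions[0].footprints, sessions[1].footprints
        )
        match_result = matcher.result_
        pairs = pd.DataFrame(
            matcher.result_.pairs,
            columns=["index1", "index2", "correlation", "distance_px"],
        )
        _write_csv(pairs, outdir / "matches.csv")
        ov = matcher.overlap_
        summary = pd.DataFrame(
            [
                {
                    "n_matched": ov.n_matched,
                    "n1": ov.n1,
                    "n2": ov.n2,
                    "overlap_index": ov.index,
                    "shift_dx": matcher.shift_[0],
                    "shift_dy": matcher.shift_[1],
                }
            ]
        )
        _write_csv(summary, outdir / "overlap.csv")
        outputs += [outdir / "matches.csv", outdir / "overlap.csv"]
        bundle["match"] = matcher.result_
        bundle["overlap_index"] = ov.index
        log.info("match: %d pairs, overlap index %.3f", ov.n_matched, ov.index)

    universe_rates = None
    if match_result is not None and len(rate_tables) == 2:
        # joint universe: matched cells once, unmatched cells of both sessions
        r1 = rate_tables[0]["rate_events_per_s"].to_numpy()
        r2 = rate_tables[1]["rate_events_per_s"].to_numpy()
        m1 = {i: j for i, j, *_ in match_result.pairs}
        only2 = [j for j in range(len(r2)) if j not in set(m1.values())]
        u = len(r1) + len(only2)
        ua = np.full(u, np.nan)
        ub = np.full(u, np.nan)
        ua[: len(r1)] = r1
        for i, j in m1.items():
            ub[i] = r2[j]
        for k, j in enumerate(only2):
            ub[len(r1) + k] = r2[j]
        universe_rates = (ua, ub)

    if "allocate" in cfg:
        if universe_rates is None:
            raise InvalidConfigError("allocate stage requires detect + match results")
        q = float(cfg["allocate"].get("q", 0.10))
        q_b = float(cfg["allocate"].get("q_b", q))
        ua, ub = universe_rates
        top_a = alloc.top_fraction(np.nan_to_num(ua, nan=0.0), q, "session1")
        top_b = alloc.top_fraction(np.nan_to_num(ub, nan=0.0), q_b, "session2")
        prob = alloc.joint_percentile_probability(top_a, top_b, universe=len(ua))
        res = pd.DataFrame(
            [
                {
                    "n_joint": prob.n_joint,
                    "universe": prob.universe,
                    "p_observed": prob.p_observed,
                    "chance": prob.chance,
                    "normalized": prob.normalized,
                }
            ]
        )
        _write_csv(res, outdir / "allocation.csv")
        outputs.append(outdir / "allocation.csv")
        bundle["allocation"] = prob
        log.info("allocate: normalized joint probability %.3f", prob.normalized)

    if "permtest" in cfg:
        if universe_rates is None:
            raise InvalidConfigError("permtest stage requires detect + match results")
        blk = cfg["permtest"]
        params = perm.PermutationParams(
            n_shuffles=int(blk.get("n_shuffles", 1000)),
            q=float(blk.get("q", 0.10)),
            seed=seed,
            exclude_triple=bool(blk.get("exclude_triple", True)),
            plus_one_correction=bool(blk.get("plus_one_correction", False)),
        )
        ua, ub = universe_rates
        results = perm.permutation_test(
            np.nan_to_num(ua, nan=0.0), np.nan_to_num(ub, nan=0.0), None, params
        )
        rows = [
            {
                "comparison": r.comparison,
                "real_overlap": r.real_overlap,
                "null_mean": float(np.nanmean(r.null_overlaps)),
                "p_value": r.p_value,
            }
            for r in results.values()
        ]
        _write_csv(pd.DataFrame(rows), outdir / "permtest.csv")
        outputs.append(outdir / "permtest.csv")
        bundle["permtest"] = results
        log.info("permtest: %s", rows)

    manifest = {
        "seed": seed,
        "config": {k: cfg[k] for k in sorted(cfg) if k in _TOP_KEYS},
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    bundle["manifest"] = manifest
    return bundle
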