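"""End-to-end orchestration: simulate -> preprocess -> extract -> crossval ->
analyze -> report.

Each stage reads only files written by earlier stages into the run directory
and writes its own outputs there, so stages can be re-run individually. A
manifest with a config hash and per-file digests makes full runs verifiable:
re-running with the same config reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activation, crossval, io, signal_prep, synergy, synthetic

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "STAGES"]

log = logging.getLogger("synergait")

STAGES = ("simulate", "preprocess", "extract", "crossval", "analyze", "report")

_DEFAULT_GROUPS: dict[str, dict] = {
    "TF": {"n_subjects": 14, "group_effect": "tf_like"},
    "C_SS": {"n_subjects": 12},
    "C_SL": {"n_subjects": 12, "stride_duration_mean_s": 1.3},
}


@dataclass
class RunConfig:
    """All knobs of a full analysis run."""

    seed: int = 0
    out_dir: str = "synergait_run"
    groups: dict[str, dict] = field(default_factory=lambda: {
        g: dict(v) for g, v in _DEFAULT_GROUPS.items()
    })
    reference_group: str = "C_SS"
    filter_low_hz: float = 35.0
    filter_high_hz: float = 450.0
    filter_order: int = 4
    envelope_method: str = "fixed_rms"
    envelope_window_ms: float = 100.0
    vaf_threshold: float = 0.90
    restarts: int = 20
    max_iter: int = 1000
    tol: float = 1e-5
    sparse_frac: float = 0.5
    n_max: int = 12
    n_shuffles: int = 200
    percentile: float = 95.0
    alpha: float = 0.05
    posthoc: str = "mannwhitney"

    def __post_init__(self) -> None:
        if not 0 < self.vaf_threshold < 1:
            raise ValueError("vaf_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if self.reference_group not in self.groups:
            raise ValueError(
                f"reference group {self.reference_group!r} not among {list(self.groups)}"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages_run: list[str]
    digests: dict[str, str]
    started_at: str
    finished_at: str
    log_path: str


def _derive_seed(base: int, *tokens) -> int:
    crc = zlib.crc32("/".join(str(t) for t in tokens).encode())
    return int(np.random.SeedSequence([base, crc]).generate_state(1)[0])


def _dirs(config: RunConfig) -> dict[str, Path]:
    root = Path(config.out_dir)
    return {s: root / s for s in STAGES} | {"root": root}


def _cohort_config(config: RunConfig, group: str) -> synthetic.CohortConfig:
    overrides = dict(config.groups[group])
    overrides.setdefault("n_subjects", 8)
    return synthetic.CohortConfig(
        group_label=group,
        seed=_derive_seed(config.seed, "simulate", group),
        **overrides,
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig) -> None:
    d = _dirs(config)
    meta: dict[str, dict] = {}
    for group in config.groups:
        cohort_cfg = _cohort_config(config, group)
        bundle = synthetic.generate_cohort(cohort_cfg)
        gdir = d["simulate"] / group
        gdir.mkdir(parents=True, exist_ok=True)
        for subj in bundle.subjects:
            io.write_emg(gdir / f"{subj.subject_id}_emg.csv", subj.recording)
            io.write_events(gdir / f"{subj.subject_id}_events.csv", subj.events)
            io.write_matrix(
                gdir / f"{subj.subject_id}_Wtrue.csv",
                subj.W_subject,
                row_labels=bundle.template.muscle_labels,
                col_labels=[f"syn{j+1}" for j in range(subj.W_subject.shape[1])],
            )
        meta[group] = {
            "mode": cohort_cfg.mode,
            "fs": cohort_cfg.sampling_rate_hz,
            "subjects": [s.subject_id for s in bundle.subjects],
        }
        log.info("simulate: group %s, %d subjects", group, len(bundle.subjects))
    with (d["simulate"] / "meta.json").open("w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def _load_meta(config: RunConfig) -> dict:
    path = _dirs(config)["simulate"] / "meta.json"
    if not path.exists():
        raise FileNotFoundError(f"run the simulate stage first ({path} missing)")
    with path.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def stage_preprocess(config: RunConfig) -> None:
    d = _dirs(config)
    meta = _load_meta(config)
    for group, info in meta.items():
        gdir = d["preprocess"] / group
        gdir.mkdir(parents=True, exist_ok=True)
        for sid in info["subjects"]:
            rec = io.read_emg(d["simulate"] / group / f"{sid}_emg.csv")
            events = io.read_events(d["simulate"] / group / f"{sid}_events.csv")
            if info["mode"] == "raw":
                rec = signal_prep.bandpass_filter(
                    rec, config.filter_low_hz, config.filter_high_hz, config.filter_order
                )
                env = signal_prep.compute_envelope(
                    rec, config.envelope_method, config.envelope_window_ms
                )
            else:  # simulated envelopes: already nonnegative activations
                env = signal_prep.EnvelopeMatrix(
                    rec.samples, muscle_labels=rec.muscle_labels
                )
            env = signal_prep.segment_strides(env, events, rec.fs)
            env = signal_prep.normalize_amplitude(env)
            io.write_envelope(gdir / f"{sid}_envelope.csv", env)

            phases = signal_prep.parse_phases(events)
            abs_bounds = signal_prep.phase_sample_bounds(phases, rec.fs)
            rel = abs_bounds - abs_bounds[:, :1] + env.stride_boundaries[:-1, None]
            with (gdir / f"{sid}_phases.csv").open("w", encoding="utf-8") as fh:
                fh.write("stride,b0,b1,b2,b3,b4\n")
                for k, row in enumerate(rel):
                    fh.write(f"{k}," + ",".join(str(int(b)) for b in row) + "\n")
        log.info("preprocess: group %s done", group)


def _read_phases(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1, dtype=int, ndmin=2)[:, 1:]


def stage_extract(config: RunConfig) -> None:
    d = _dirs(config)
    meta = _load_meta(config)
    kw = dict(
        restarts=config.restarts,
        max_iter=config.max_iter,
        tol=config.tol,
        sparse_frac=config.sparse_frac,
    )
    d["extract"].mkdir(parents=True, exist_ok=True)

    orders: dict[str, dict[str, int]] = {}
    for group, info in meta.items():
        orders[group] = {}
        for sid in info["subjects"]:
            env = io.read_envelope(d["preprocess"] / group / f"{sid}_envelope.csv")
            orders[group][sid] = synergy.select_order(
                env,
                threshold=config.vaf_threshold,
                n_max=config.n_max,
                seed=_derive_seed(config.seed, "order", group, sid),
                **kw,
            )
        log.info("extract: group %s orders %s", group, orders[group])
    group_orders = {g: synergy.group_order(list(o.values())) for g, o in orders.items()}
    n_common = group_orders[config.reference_group]
    with (d["extract"] / "orders.json").open("w", encoding="utf-8") as fh:
        json.dump(
            {"per_subject": orders, "per_group": group_orders, "n_common": n_common},
            fh, indent=1, sort_keys=True,
        )

    # fixed-order extraction, normalization and ordering against one anchor
    anchor: np.ndarray | None = None
    decomposed: dict[str, dict[str, synergy.SynergyDecomposition]] = {}
    ordered: dict[str, list[np.ndarray]] = {}
    group_list = [config.reference_group] + [
        g for g in meta if g != config.reference_group
    ]
    for group in group_list:
        gdir = d["extract"] / group
        gdir.mkdir(parents=True, exist_ok=True)
        decomposed[group] = {}
        ordered[group] = []
        for sid in meta[group]["subjects"]:
            env = io.read_envelope(d["preprocess"] / group / f"{sid}_envelope.csv")
            dec = synergy.nnmf_extract(
                env, n_common,
                seed=_derive_seed(config.seed, "extract", group, sid), **kw,
            )
            dec = synergy.normalize_synergies(dec)
            if anchor is None:
                anchor = dec.W
            perm, _ = synergy.order_synergies(dec.W, anchor)
            dec = dataclasses.replace(dec, W=dec.W[:, perm], H=dec.H[perm, :])
            decomposed[group][sid] = dec
            ordered[group].append(dec.W)
            labels = list(env.muscle_labels or [])
            syn_labels = [f"syn{j+1}" for j in range(n_common)]
            io.write_matrix(gdir / f"{sid}_W.csv", dec.W, labels, syn_labels)
            io.write_matrix(
                gdir / f"{sid}_H.csv", dec.H, syn_labels,
                [str(t) for t in range(dec.H.shape[1])],
            )
            with (gdir / f"{sid}_meta.json").open("w", encoding="utf-8") as fh:
                json.dump(
                    {"vaf": dec.vaf, "n_syn": dec.n_syn, "converged": dec.converged},
                    fh, indent=1, sort_keys=True,
                )

    muscle_labels = None
    for group in group_list:
        gset = synergy.average_synergies(ordered[group])
        env0 = io.read_envelope(
            d["preprocess"] / group / f"{meta[group]['subjects'][0]}_envelope.csv"
        )
        muscle_labels = list(env0.muscle_labels or [])
        io.write_matrix(
            d["extract"] / f"{group}_Wmean.csv", gset.W_mean,
            muscle_labels, [f"syn{j+1}" for j in range(n_common)],
        )
    wctrl, _, _ = io.read_matrix(d["extract"] / f"{config.reference_group}_Wmean.csv")
    io.write_matrix(
        d["extract"] / "wctrl.csv", wctrl, muscle_labels,
        [f"syn{j+1}" for j in range(n_common)],
    )

    sims = {}
    for group in group_list:
        W_g, _, _ = io.read_matrix(d["extract"] / f"{group}_Wmean.csv")
        perm, s = synergy.order_synergies(W_g, wctrl)
        sims[group] = list(map(float, s))
    with (d["extract"] / "similarity.json").open("w", encoding="utf-8") as fh:
        json.dump(sims, fh, indent=1, sort_keys=True)


def stage_crossval(config: RunConfig) -> None:
    d = _dirs(config)
    meta = _load_meta(config)
    wctrl, _, _ = io.read_matrix(d["extract"] / "wctrl.csv")
    d["crossval"].mkdir(parents=True, exist_ok=True)
    rows = []
    for group, info in meta.items():
        for sid in info["subjects"]:
            env = io.read_envelope(d["preprocess"] / group / f"{sid}_envelope.csv")
            seed = _derive_seed(config.seed, "crossval", group, sid)
            res = crossval.cross_validate(
                env, wctrl,
                n_shuffles=config.n_shuffles, seed=seed,
                percentile=config.percentile,
                max_iter=config.max_iter, tol=config.tol,
            )
            rows.append(
                {
                    "group": group,
                    "subject": sid,
                    "vaf_recon": res.vaf_recon,
                    "vaf_threshold": res.vaf_threshold,
                    "representative": res.representative,
                    "n_shuffles": res.n_shuffles,
                    "seed": seed,
                }
            )
        log.info("crossval: group %s done", group)
    pd.DataFrame(rows).to_csv(d["crossval"] / "results.csv", index=False)


def stage_analyze(config: RunConfig) -> None:
    d = _dirs(config)
    meta = _load_meta(config)
    wctrl, _, _ = io.read_matrix(d["extract"] / "wctrl.csv")
    d["analyze"].mkdir(parents=True, exist_ok=True)

    records = []
    for group, info in meta.items():
        for sid in info["subjects"]:
            env = io.read_envelope(d["preprocess"] / group / f"{sid}_envelope.csv")
            bounds = _read_phases(d["preprocess"] / group / f"{sid}_phases.csv")
            H = crossval.nnr_fit(
                env, wctrl,
                max_iter=config.max_iter, tol=config.tol,
                seed=_derive_seed(config.seed, "analyze", group, sid),
            )
            profiles = []
            for k in range(env.n_strides):
                b = bounds[k]
                h_stride = H[:, b[0] : b[4]]
                profiles.append(
                    signal_prep.time_normalize(h_stride, b - b[0]).values
                )
            mean = signal_prep.mean_profile(np.stack(profiles))
            records.append((sid, group, mean.values))

    table = activation.build_phase_activity_table(records)
    table.to_csv(d["analyze"] / "phase_activity.csv", index=False)

    result = activation.kruskal_wallis_by_cell(
        table, alpha=config.alpha, posthoc=config.posthoc
    )
    result.cells.to_csv(d["analyze"] / "kw_cells.csv", index=False)
    result.posthoc.to_csv(d["analyze"] / "posthoc.csv", index=False)

    with (d["extract"] / "orders.json").open("r", encoding="utf-8") as fh:
        orders = json.load(fh)["per_subject"]
    levels = sorted({n for g in orders.values() for n in g.values()})
    groups = list(meta)
    counts = [
        [sum(1 for n in orders[g].values() if n == lv) for lv in levels]
        for g in groups
    ]
    fisher_p = (
        activation.synergy_count_test(np.asarray(counts)) if len(levels) > 1 else 1.0
    )
    with (d["analyze"] / "fisher.json").open("w", encoding="utf-8") as fh:
        json.dump(
            {"groups": groups, "order_levels": levels, "counts": counts, "p": fisher_p},
            fh, indent=1, sort_keys=True,
        )


def stage_report(config: RunConfig) -> None:
    d = _dirs(config)
    d["report"].mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    with (d["extract"] / "orders.json").open("r", encoding="utf-8") as fh:
        summary["orders"] = json.load(fh)
    with (d["extract"] / "similarity.json").open("r", encoding="utf-8") as fh:
        summary["mean_synergy_similarity_vs_wctrl"] = json.load(fh)
    cv = pd.read_csv(d["crossval"] / "results.csv")
    summary["crossval"] = {
        "fraction_representative": float(cv["representative"].mean()),
        "mean_vaf_recon": float(cv["vaf_recon"].mean()),
    }
    cells = pd.read_csv(d["analyze"] / "kw_cells.csv")
    summary["significant_cells"] = cells.loc[
        cells["significant"], ["synergy", "phase", "p"]
    ].to_dict("records")
    with (d["analyze"] / "fisher.json").open("r", encoding="utf-8") as fh:
        summary["synergy_count_test"] = json.load(fh)
    with (d["report"] / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)


_STAGE_FNS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "extract": stage_extract,
    "crossval": stage_crossval,
    "analyze": stage_analyze,
    "report": stage_report,
}


def _digest_tree(root: Path, exclude: tuple[str, ...] = ("manifest.json",)) -> dict[str, str]:
    digests = {}
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.name not in exclude:
            digests[str(path.relative_to(root))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return digests


def run_pipeline(config: RunConfig, stages=None) -> RunManifest:
    """Run the requested stages (default: all) and write the run manifest."""
    stages = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in stages if s not in _STAGE_FNS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    log_path = root / "run.log"
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    config.to_yaml(root / "config.yaml")
    for stage in stages:
        log.info("running stage %s", stage)
        try:
            _STAGE_FNS[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = RunManifest(
        version="1.0.0",
        config_hash=config.config_hash(),
        seed=config.seed,
        stages_run=stages,
        digests=_digest_tree(root, exclude=("manifest.json", "run.log")),
        started_at=started,
        finished_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
        log_path=str(log_path),
    )
    with (root / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=1, sort_keys=True)
    return manifest
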