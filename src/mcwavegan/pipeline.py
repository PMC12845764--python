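"""End-to-end orchestration: configuration, staged runs, manifests.

Two entry points:

* :func:`run_desk_experiment` — the in-memory scaled-down experiment
  (fixtures -> GAN -> generate -> β-sweep refinement -> classify ->
  distribution comparison) used by the test harness and the
  reproduction script;
* :func:`run_pipeline` — the file-based staged pipeline behind
  ``mcwavegan run``, with per-stage manifests and hash-based skipping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import EVENT_CLASSES, SegmentSet
from .classify import LdaSvmClassifier
from .features import FeatureConfig, desk_feature_config
from .fixtures import FixtureConfig, gen_dataset, write_fixture_dir
from .preprocess import PreprocessConfig, desk_preprocess_config, load_wav, preprocess_pipeline, write_wav
from .refine import RefineConfig, refine, sweep_beta
from .stats_compare import compare_report, divergence_table
from .wavegan import make_config, select_converged, train, generate

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


_SECTION_TYPES = {
    "fixtures": FixtureConfig,
    "preprocess": PreprocessConfig,
    "features": FeatureConfig,
}

_RUN_KEYS = {
    "seed", "out_root", "log_level", "profile", "target_label",
    "n_clips_per_class", "n_pool", "betas", "n_out", "max_iters",
    "fixtures", "preprocess", "features", "gan",
}


@dataclass
class RunConfig:
    """Fully-resolved configuration of a staged run.

    ``profile`` selects the scale ("desk" or "paper"); section dicts
    override individual fields of the per-module config types.  Unknown
    keys are rejected at parse time.
    """

    seed: int = 0
    out_root: str = "runs"
    log_level: str = "INFO"
    profile: str = "desk"
    target_label: str = "QueenPresent"
    n_clips_per_class: int = 20
    n_pool: int = 500
    betas: tuple = (0.01, 0.5, 0.9)
    n_out: int = 500
    max_iters: int | None = None
    fixtures: FixtureConfig = field(default_factory=FixtureConfig)
    preprocess: PreprocessConfig = field(default_factory=desk_preprocess_config)
    features: FeatureConfig = field(default_factory=desk_feature_config)
    gan: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.profile not in ("desk", "paper"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.target_label not in EVENT_CLASSES:
            raise ValueError(f"target_label must be one of {EVENT_CLASSES}")
        for beta in self.betas:
            if not (0.0 <= float(beta) <= 1.0):
                raise ValueError(
                    f"beta {beta} violates the bound 0≤β≤1"
                )


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse YAML text (or a dict) into a :class:`RunConfig`.

    Fills defaults, rejects unknown keys, and range-checks fields via
    the dataclass validators.
    """
    if raw is None or raw == "":
        data = {}
    elif isinstance(raw, dict):
        data = dict(raw)
    else:
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ValueError("run configuration must be a mapping")
    unknown = set(data) - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES and isinstance(value, dict):
            cls = _SECTION_TYPES[key]
            valid = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - valid
            if bad:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(bad)}")
            base = desk_preprocess_config() if cls is PreprocessConfig else cls()
            if cls is FeatureConfig:
                base = desk_feature_config()
            kwargs[key] = dataclasses.replace(base, **value)
        elif key == "betas":
            kwargs[key] = tuple(float(b) for b in value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# the in-memory desk experiment


def run_desk_experiment(
    seed: int,
    target_label: str = "QueenPresent",
    n_clips_per_class: int = 20,
    n_pool: int = 500,
    betas: tuple = (0.01, 0.5, 0.9),
    n_out: int = 500,
    max_iters: int | None = None,
    gan_overrides: dict | None = None,
) -> dict:
    """Scaled-down end-to-end experiment, all in memory.

    Returns a dict with the fixture data, fitted reference classifier,
    GAN loss trace, selected checkpoint iteration, raw-pool class
    fraction, the β-sweep table, and per-β divergence tables.
    """
    pp = desk_preprocess_config()
    fc = desk_feature_config()
    data = gen_dataset(n_per_class=n_clips_per_class, cfg=FixtureConfig(),
                       seed=seed, preprocess=pp)
    model = LdaSvmClassifier(rate=data.rate, feature_config=fc)
    model.fit_segments(data)

    reals = data.filter_label(target_label)
    gan_cfg = make_config("desk", seed=seed, **(gan_overrides or {}))
    series = train(reals, gan_cfg)
    best_iter, ckpt = select_converged(series, model, target_label)
    pool = generate(ckpt, n_pool, seed=seed + 100)
    raw_frac = float(np.mean(model.predict(pool.segments) == target_label))

    # per-β refinement + classification; the assembled table matches the
    # sweep_beta layout (one refinement per β, best = argmax target count,
    # earliest on ties)
    import pandas as pd

    divergences = {}
    refined_sets = {}
    rows = []
    alphabet = list(model.classes_)
    for beta in betas:
        cfg_b = RefineConfig(beta=beta, n_out=n_out, seed=seed + 200,
                             max_iters=max_iters, feature_config=fc)
        r = refine(pool, reals, cfg_b)
        refined_sets[beta] = r
        pred = model.predict(r.clips.segments)
        counts = {c: int(np.sum(pred == c)) for c in alphabet}
        rows.append({"beta": beta, **counts, "n_out": len(r.clips),
                     "acceptance_rate": r.acceptance_rate})
        if len(r.clips):
            rep = compare_report(reals, pool, r.clips, n_pairs=1, seed=seed)
            divergences[beta] = divergence_table(rep)
    sweep = pd.DataFrame(rows)
    best_idx = int(sweep[target_label].to_numpy().argmax())
    sweep["best"] = False
    sweep.loc[best_idx, "best"] = True

    best_beta = float(sweep.loc[sweep["best"], "beta"].iloc[0])
    return {
        "data": data,
        "model": model,
        "losses": series.losses,
        "best_iteration": best_iter,
        "pool": pool,
        "raw_fraction": raw_frac,
        "sweep": sweep,
        "best_beta": best_beta,
        "refined": refined_sets,
        "divergences": divergences,
        "target_label": target_label,
    }


# ---------------------------------------------------------------------------
# staged file-based pipeline


@dataclass
class RunManifest:
    stage: str
    config_hash: str
    input_hash: str
    seed: int
    version: str
    started: float
    finished: float
    outputs: list

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        tmp.replace(path)  # atomic on POSIX

    @staticmethod
    def read(path: Path) -> "RunManifest | None":
        if not path.exists():
            return None
        try:
            return RunManifest(**json.loads(path.read_text()))
        except (json.JSONDecodeError, TypeError):
            return None


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_files(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(map(str, paths)):
        h.update(p.encode())
        h.update(hashlib.sha256(Path(p).read_bytes()).digest())
    return h.hexdigest()[:16]


def save_segments(segments: SegmentSet, out_dir) -> Path:
    """Write a segment set as per-clip float32 WAVs plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = segments.manifest()
    names = []
    for i in range(len(segments)):
        name = f"seg_{i:05d}.wav"
        write_wav(out_dir / name, segments.waveform(i))
        names.append(name)
    manifest.insert(0, "file", names)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def load_segments(in_dir) -> SegmentSet:
    """Inverse of :func:`save_segments`."""
    import pandas as pd

    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    waves, labels, sources, indices = [], [], [], []
    rate = None
    for _, row in manifest.iterrows():
        w = load_wav(in_dir / row["file"])
        waves.append(w.samples)
        labels.append(row["label"])
        sources.append(row["source_id"])
        indices.append(row["segment_index"])
        rate = row["rate"]
    return SegmentSet(np.stack(waves), np.asarray(labels, dtype=object), float(rate),
                      np.asarray(sources, dtype=object), np.asarray(indices, dtype=int))


def run_pipeline(cfg: RunConfig) -> list[RunManifest]:
    """Execute the staged pipeline, skipping stages whose outputs are
    current (matching config and input hashes).  A stage failure halts
    the run with the stage named; completed outputs are retained.
    """
    root = Path(cfg.out_root)
    root.mkdir(parents=True, exist_ok=True)
    (root / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, default=str)
    )
    manifests: list[RunManifest] = []
    state: dict = {"cfg": cfg}

    stages = [
        ("fixtures", _stage_fixtures),
        ("preprocess", _stage_preprocess),
        ("train-gan", _stage_train),
        ("generate", _stage_generate),
        ("refine", _stage_refine),
        ("evaluate", _stage_evaluate),
        ("compare", _stage_compare),
    ]
    for name, fn in stages:
        stage_dir = root / name
        man_path = stage_dir / "manifest.json"
        config_hash = _hash_obj([dataclasses.asdict(cfg), name])
        input_hash = _hash_obj(state.get("chain_hash", ""))
        prev = RunManifest.read(man_path)
        if prev and prev.config_hash == config_hash and prev.input_hash == input_hash \
                and all(Path(p).exists() for p in prev.outputs):
            log.info("stage %s: outputs current, skipped", name)
            try:
                state = fn(state, stage_dir, skip=True)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {name!r} failed reloading its outputs "
                    f"(corrupted intermediate?): {exc}"
                ) from exc
            state["chain_hash"] = _hash_obj([input_hash, config_hash])
            manifests.append(prev)
            continue
        stage_dir.mkdir(parents=True, exist_ok=True)
        started = time.time()
        try:
            state = fn(state, stage_dir, skip=False)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        outputs = sorted(str(p) for p in stage_dir.glob("*") if p.name != "manifest.json")
        man = RunManifest(
            stage=name, config_hash=config_hash, input_hash=input_hash,
            seed=cfg.seed, version=__version__, started=started,
            finished=time.time(), outputs=outputs,
        )
        man.write(man_path)
        state["chain_hash"] = _hash_obj([input_hash, config_hash])
        manifests.append(man)
    return manifests


def _stage_fixtures(state, stage_dir, skip):
    cfg: RunConfig = state["cfg"]
    if not skip:
        write_fixture_dir(stage_dir, cfg.n_clips_per_class, cfg.fixtures, seed=cfg.seed)
    state["fixture_dir"] = stage_dir
    return state


def _stage_preprocess(state, stage_dir, skip):
    cfg: RunConfig = state["cfg"]
    import pandas as pd

    labels = pd.read_csv(state["fixture_dir"] / "labels.csv")
    if not skip:
        segments = preprocess_pipeline(
            [state["fixture_dir"] / f for f in labels["file"]],
            list(labels["label"]), cfg.preprocess,
        )
        save_segments(segments, stage_dir)
    state["segments"] = load_segments(stage_dir)
    return state


def _stage_train(state, stage_dir, skip):
    cfg: RunConfig = state["cfg"]
    from .wavegan import save_checkpoint, load_checkpoint

    reals = state["segments"].filter_label(cfg.target_label)
    ckpt_path = stage_dir / "checkpoint_best.npz"
    model = LdaSvmClassifier(rate=reals.rate, feature_config=cfg.features)
    model.fit_segments(state["segments"])
    state["model"] = model
    if not skip:
        gan_cfg = make_config("desk" if cfg.profile == "desk" else None,
                              seed=cfg.seed, **cfg.gan)
        series = train(reals, gan_cfg)
        best_iter, ckpt = select_converged(series, model, cfg.target_label)
        save_checkpoint(ckpt_path, ckpt)
        series.loss_frame().to_csv(stage_dir / "losses.csv", index=False)
    state["checkpoint"] = load_checkpoint(ckpt_path)
    state["reals"] = reals
    return state


def _stage_generate(state, stage_dir, skip):
    cfg: RunConfig = state["cfg"]
    if not skip:
        pool = generate(state["checkpoint"], cfg.n_pool, seed=cfg.seed + 100)
        save_segments(pool, stage_dir)
    state["pool"] = load_segments(stage_dir)
    return state


def _stage_refine(state, stage_dir, skip):
    cfg: RunConfig = state["cfg"]
    import pandas as pd

    sweep_path = stage_dir / "sweep.csv"
    ref_cfg = RefineConfig(beta=cfg.betas[0], n_out=cfg.n_out, seed=cfg.seed + 200,
                           max_iters=cfg.max_iters, feature_config=cfg.features)
    if not skip:
        table = sweep_beta(state["pool"], state["reals"], cfg.betas, ref_cfg,
                           state["model"], cfg.target_label)
        table.to_csv(sweep_path, index=False)
        best_beta = float(table.loc[table["best"], "beta"].iloc[0])
        refined = refine(state["pool"], state["reals"],
                         dataclasses.replace(ref_cfg, beta=best_beta))
        save_segments(refined.clips, stage_dir / "refined")
        pd.DataFrame(refined.features).to_csv(stage_dir / "refined_features.csv", index=False)
    state["sweep"] = pd.read_csv(sweep_path)
    state["refined"] = load_segments(stage_dir / "refined")
    return state


def _stage_evaluate(state, stage_dir, skip):
    cfg: RunConfig = state["cfg"]
    if not skip:
        from .classify import class_distribution

        pred_pool = state["model"].predict(state["pool"].segments)
        pred_ref = state["model"].predict(state["refined"].segments)
        table = class_distribution(pred_pool, state["model"].classes_)
        table["set"] = "wavegan"
        table2 = class_distribution(pred_ref, state["model"].classes_)
        table2["set"] = "refined"
        import pandas as pd

        pd.concat([table, table2]).to_csv(stage_dir / "class_distribution.csv", index=False)
    return state


def _stage_compare(state, stage_dir, skip):
    cfg: RunConfig = state["cfg"]
    if not skip:
        rep = compare_report(state["reals"], state["pool"], state["refined"],
                             n_pairs=3, seed=cfg.seed)
        divergence_table(rep).to_csv(stage_dir / "divergences.csv", index=False)
        from .stats_compare import lda_projection

        proj = lda_projection(state["model"], {
            "real": state["reals"], "wavegan": state["pool"], "refined": state["refined"],
        })
        proj.to_csv(stage_dir / "lda_projection.csv", index=False)
    return state
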