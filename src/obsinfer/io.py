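"""Readers and writers for the on-disk formats, plus seeded fixtures.

Formats (all plain text, UTF-8, '\\n' line endings):

* stimulus — one line of alphabet characters (``0101...``), or a CSV with
  ``trial,symbol`` columns;
* Markov model — JSON with order, alphabet and a context-keyed emission
  table;
* prediction trace — CSV ``trial,stimulus_symbol,predicted_symbol,
  p_emit_0,p_emit_1``;
* ensemble — wide CSV with one ``clone_i`` column per clone plus the
  per-trial empirical symbol frequencies;
* experiment config — YAML or JSON.

Probabilities are serialized with 17 significant digits so every
writer/reader pair round-trips bit-exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from .bayes import ObserverSpec
from .inference import GridSpec, reference_loglik, loglik_glm
from .observers import EnsembleTrace, PredictionTrace, simulate_observer
from .stimuli import (
    Alphabet,
    BINARY,
    MarkovModel,
    SymbolSequence,
    generate_stimulus,
    sample_markov_model,
)

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_model",
    "write_model",
    "read_trace",
    "write_trace",
    "ExperimentConfig",
    "load_config",
    "make_fixtures",
]

_P = "{:.17g}".format  # probability serialization: exact float round-trip


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    return "csv" if path.suffix.lower() == ".csv" else "txt"


def read_sequence(
    path, format: Optional[str] = None, alphabet: Alphabet = BINARY
) -> SymbolSequence:
    """Read a stimulus/prediction sequence from txt or CSV.

    Invalid characters raise with the 1-based line and column position.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "txt":
        line = path.read_text().splitlines()
        text = line[0].rstrip() if line else ""
        lookup = {tok: i for i, tok in enumerate(alphabet.symbols)}
        for col, ch in enumerate(text, start=1):
            if ch not in lookup:
                raise ValueError(
                    f"{path}: invalid symbol {ch!r} at line 1, column {col}"
                )
        return SymbolSequence([lookup[ch] for ch in text], alphabet)
    if fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "symbol" not in reader.fieldnames:
                raise ValueError(f"{path}: CSV must have a 'symbol' column")
            lookup = {tok: i for i, tok in enumerate(alphabet.symbols)}
            out = []
            for lineno, row in enumerate(reader, start=2):
                tok = row["symbol"].strip()
                if tok not in lookup:
                    raise ValueError(
                        f"{path}: invalid symbol {tok!r} at line {lineno}"
                    )
                out.append(lookup[tok])
        return SymbolSequence(out, alphabet)
    raise ValueError(f"unknown sequence format {fmt!r}")


def write_sequence(seq: SymbolSequence, path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "txt":
        path.write_text(seq.to_string() + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["trial", "symbol"])
            for t, s in enumerate(seq.symbols, start=1):
                writer.writerow([t, seq.alphabet.symbols[s]])
    else:
        raise ValueError(f"unknown sequence format {fmt!r}")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def write_model(model: MarkovModel, path) -> None:
    Path(path).write_text(model.to_json() + "\n")


def read_model(path) -> MarkovModel:
    return MarkovModel.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace(trace: PredictionTrace | EnsembleTrace, path, stimulus=None) -> None:
    """Write a single-observer or ensemble trace as CSV.

    Single traces use the columns (trial, stimulus_symbol,
    predicted_symbol, p_emit_0, p_emit_1); ensembles get one clone_i
    column per clone plus per-trial empirical frequencies.
    """
    path = Path(path)
    if isinstance(trace, PredictionTrace):
        stim = stimulus if stimulus is not None else trace.stimulus
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(
                ["trial", "stimulus_symbol", "predicted_symbol", "p_emit_0", "p_emit_1"]
            )
            for t in range(len(trace)):
                writer.writerow(
                    [
                        t + 1,
                        "" if stim is None else int(stim.symbols[t]),
                        "" if trace.predictions is None else int(trace.predictions[t]),
                        _P(trace.emission_probs[t, 0]),
                        _P(trace.emission_probs[t, 1]),
                    ]
                )
        return
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        n = trace.n_clones
        writer.writerow(
            ["trial"]
            + [f"clone_{i}" for i in range(n)]
            + ["freq_0", "freq_1"]
        )
        for t in range(trace.n_trials):
            writer.writerow(
                [t + 1]
                + [int(trace.prediction_matrix[i, t]) for i in range(n)]
                + [_P(trace.empirical_freqs[t, 0]), _P(trace.empirical_freqs[t, 1])]
            )


def read_trace(path, alphabet: Alphabet = BINARY) -> PredictionTrace:
    """Read a single-observer trace CSV written by :func:`write_trace`."""
    path = Path(path)
    stim, preds, probs = [], [], []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            if row["stimulus_symbol"] != "":
                stim.append(int(row["stimulus_symbol"]))
            if row["predicted_symbol"] != "":
                preds.append(int(row["predicted_symbol"]))
            probs.append([float(row["p_emit_0"]), float(row["p_emit_1"])])
    return PredictionTrace(
        emission_probs=np.array(probs) if probs else np.empty((0, alphabet.size)),
        predictions=np.array(preds, dtype=np.int64) if preds else None,
        stimulus=SymbolSequence(stim, alphabet) if stim else None,
    )


# ---------------------------------------------------------------------------
# experiment config
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Parsed experiment description (stimulus, observers, inference)."""

    seed: int = 0
    stimulus_order: int = 2
    stimulus_length: int = 500
    concentration: float = 1.0
    model_file: Optional[str] = None
    observers: List[ObserverSpec] = field(default_factory=list)
    n_clones: int = 1
    grids: Dict[str, GridSpec] = field(default_factory=dict)
    r_max: int = 8
    tol: float = 1e-9
    n_per_class: int = 20
    replicates: int = 3
    orders: List[int] = field(default_factory=lambda: [2])
    lengths: List[int] = field(default_factory=lambda: [500])

    @classmethod
    def from_dict(cls, obj: dict) -> "ExperimentConfig":
        cfg = cls()
        stim = obj.get("stimulus", {})
        cfg.stimulus_order = int(stim.get("order", cfg.stimulus_order))
        cfg.stimulus_length = int(stim.get("length", cfg.stimulus_length))
        cfg.concentration = float(stim.get("concentration", cfg.concentration))
        cfg.model_file = stim.get("model_file")
        cfg.seed = int(obj.get("seed", cfg.seed))
        obs = obj.get("observers", [])
        cfg.observers = [_spec_from_dict(o) for o in obs]
        cfg.n_clones = int(obj.get("n_clones", cfg.n_clones))
        inf = obj.get("inference", {})
        cfg.r_max = int(inf.get("r_max", cfg.r_max))
        cfg.tol = float(inf.get("tol", cfg.tol))
        for name, g in inf.get("grids", {}).items():
            cfg.grids[name] = GridSpec(
                alphas=tuple(g.get("alphas", ())),
                betas=tuple(g.get("betas", ())),
                gammas=tuple(g.get("gammas", ())),
                windows=tuple(g.get("windows", ())),
            )
        exp = obj.get("experiment", {})
        cfg.n_per_class = int(exp.get("n_per_class", cfg.n_per_class))
        cfg.replicates = int(exp.get("replicates", cfg.replicates))
        cfg.orders = [int(r) for r in exp.get("orders", cfg.orders)]
        cfg.lengths = [int(n) for n in exp.get("lengths", cfg.lengths)]
        return cfg


def _spec_from_dict(o: dict) -> ObserverSpec:
    kwargs = {k: o[k] for k in ("strategy", "alpha", "beta", "gamma", "window", "ridge")
              if k in o}
    if "window" in kwargs and kwargs["window"] is not None:
        kwargs["window"] = int(kwargs["window"])
    return ObserverSpec(**kwargs)


def load_config(path) -> ExperimentConfig:
    """Load an experiment config from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        obj = json.loads(text)
    else:
        obj = yaml.safe_load(text)
    if not isinstance(obj, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return ExperimentConfig.from_dict(obj)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(seed: int = 0, outdir=None, length: int = 300, r_max: int = 4) -> dict:
    """Deterministic small bundle used by the test suite.

    An order-2 model, a stimulus, one simulated trace per strategy and
    the three log likelihoods computed by the slow reference path
    (counts rebuilt from scratch at every trial).  Writing the same seed
    twice yields byte-identical files.
    """
    root = np.random.SeedSequence(seed)
    model_s, stim_s, *obs_s = root.spawn(5)
    model = sample_markov_model(2, concentration=1.0, seed=np.random.default_rng(model_s))
    stimulus = generate_stimulus(model, length, seed=np.random.default_rng(stim_s))
    specs = {
        "ngram_argmax": ObserverSpec("ngram_argmax", alpha=2.0, beta=1.0, gamma=0.5),
        "ngram_average": ObserverSpec("ngram_average", alpha=1.0, beta=0.5, gamma=1.0),
        "glm": ObserverSpec("glm", window=2),
    }
    traces, logliks = {}, {}
    for (name, spec), s in zip(specs.items(), obs_s):
        trace = simulate_observer(spec, stimulus, seed=np.random.default_rng(s),
                                  r_max=r_max)
        traces[name] = trace
        if name == "glm":
            logliks[name] = loglik_glm(stimulus, trace, spec.window, spec.ridge)
        else:
            logliks[name] = reference_loglik(stimulus, trace, spec, r_max=r_max)
    bundle = {
        "model": model,
        "stimulus": stimulus,
        "specs": specs,
        "traces": traces,
        "reference_logliks": logliks,
        "r_max": r_max,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_model(model, outdir / "model.json")
        write_sequence(stimulus, outdir / "stimulus.txt")
        for name, trace in traces.items():
            write_trace(trace, outdir / f"trace_{name}.csv")
        (outdir / "reference_logliks.json").write_text(
            json.dumps({k: float(v) for k, v in logliks.items()}, indent=1,
                       sort_keys=True)
            + "\n"
        )
    return bundle
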