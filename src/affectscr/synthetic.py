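"""Synthetic affective SCR data generator.

Emulates the statistical structure of a 3-class picture-viewing experiment:
8 stimuli per affect class (pleasant / neutral / unpleasant) whose SCR
parameters (onset time, gain, rise time, decay time constant) cluster by
class, with valence and arousal ratings on the 1-9 SAM scale produced by a
known ground-truth polynomial of (gain, decay time constant) plus rating
noise.  Raw 10 s post-stimulus conductance segments are synthesized from the
six-parameter SC model (SCR riding on a decaying previous response plus a
tonic level) with additive Gaussian sensor noise.

Everything is deterministic under the config seed, and the ground truth is
returned alongside the data so that parameter- and coefficient-recovery can
be checked end to end.  The default mapping is synthetic: it qualitatively
mirrors a gain-dominated arousal response and a mixed valence response, and
is not an empirical model of any real data set.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidParameterError
from .hmpr import PolynomialModel
from .scr import SCParams, SCRParams, SCTrace, sc_waveform

__all__ = [
    "ClassParams",
    "GeneratorConfig",
    "generate_feature_table",
    "generate_sc_traces",
    "default_affective_config",
    "linear_affective_config",
]

FEATURE_SCHEMA = (
    "stimulus_id", "affect_class", "onset_time", "gain", "rise_time",
    "decay_time_constant", "valence", "arousal", "provenance",
)


@dataclass(frozen=True)
class ClassParams:
    """Per-class (mean, sd) of each SCR parameter, in s / uS / s / s."""

    onset_time: tuple[float, float]
    gain: tuple[float, float]
    rise_time: tuple[float, float]
    decay_time_constant: tuple[float, float]


# Ground-truth rating maps: exponent tuple over (gain, decay_time_constant)
# -> coefficient.  Chosen so the three class centres land near valence
# 7 / 5 / 2.5 and arousal 5.5 / 3 / 6 on the 1-9 scale.
_VALENCE_TRUTH = {(0, 0): 4.221053, (1, 0): -4.368421,
                  (0, 1): 0.442105, (1, 1): 1.0}
_AROUSAL_TRUTH = {(0, 0): 0.815789, (1, 0): 4.473684, (0, 1): 0.131579}

# Affine variant hitting the same class centres: the pairwise extension
# commutes exactly with affine maps, so this truth survives
# extend -> fit -> evaluate without bias (used for closed-loop checks).
_VALENCE_TRUTH_LINEAR = {(0, 0): 1.447368, (1, 0): -1.578947, (0, 1): 1.394737}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic generator."""

    n_per_class: int = 8
    classes: dict = field(default_factory=dict)
    valence_coef: dict = field(default_factory=lambda: dict(_VALENCE_TRUTH))
    arousal_coef: dict = field(default_factory=lambda: dict(_AROUSAL_TRUTH))
    rating_noise_sd: float = 0.3
    trace_noise_sd: float = 0.01
    sampling_rate: float = 100.0
    segment_length: float = 10.0
    a0_range: tuple[float, float] = (0.1, 0.5)
    c_range: tuple[float, float] = (1.0, 3.0)
    #: clip ratings to the 1-9 scale (the scale censors extreme draws);
    #: disable to study the uncensored ground-truth map
    clip_ratings: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 0:
            raise InvalidParameterError("n_per_class must be >= 0")
        for name in ("rating_noise_sd", "trace_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.classes and len(self.classes) < 2:
            raise InvalidParameterError("need at least 2 affect classes")

    def true_model(self, target: str) -> PolynomialModel:
        """Ground-truth rating polynomial as a PolynomialModel."""
        coefs = {"valence": self.valence_coef,
                 "arousal": self.arousal_coef}[target]
        exps = tuple(tuple(e) for e in coefs)
        vals = np.array([coefs[e] for e in coefs], dtype=float)
        order = max(sum(e) for e in exps)
        return PolynomialModel(
            num_vars=2, order=order, exponents=exps, coefficients=vals,
            coef_se=np.zeros(len(vals)), coef_p=np.zeros(len(vals)),
            target_label=target,
            var_names=("gain", "decay_time_constant"),
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["valence_coef"] = {" ".join(map(str, k)): v
                                for k, v in self.valence_coef.items()}
        data["arousal_coef"] = {" ".join(map(str, k)): v
                                for k, v in self.arousal_coef.items()}
        data["classes"] = {k: asdict(v) if isinstance(v, ClassParams) else v
                           for k, v in self.classes.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("valence_coef", "arousal_coef"):
            data[key] = {tuple(int(x) for x in k.split()): float(v)
                         for k, v in data[key].items()}
        data["classes"] = {
            k: ClassParams(**{f: tuple(v[f]) for f in v})
            for k, v in data["classes"].items()
        }
        for key in ("a0_range", "c_range"):
            data[key] = tuple(data[key])
        return cls(**data)


_DEFAULT_CLASSES = {
    "pleasant": ClassParams(onset_time=(1.2, 0.10), gain=(0.9, 0.08),
                            rise_time=(0.7, 0.08),
                            decay_time_constant=(5.0, 0.30)),
    "neutral": ClassParams(onset_time=(1.5, 0.10), gain=(0.4, 0.08),
                           rise_time=(0.6, 0.08),
                           decay_time_constant=(3.0, 0.30)),
    "unpleasant": ClassParams(onset_time=(1.0, 0.10), gain=(1.1, 0.08),
                              rise_time=(0.8, 0.08),
                              decay_time_constant=(2.0, 0.30)),
}


def default_affective_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default 3-class x 8-stimulus configuration.

    Class (gain, decay-constant) centres are well separated (emulating SCR
    waveforms that cluster by affect class) and the ground-truth rating map
    is a second-order polynomial with a gain-dominated arousal component and
    a mixed valence component including a gain x decay interaction.
    """
    kwargs = dict(classes=dict(_DEFAULT_CLASSES), seed=seed)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def linear_affective_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Affine-ground-truth, noise-free variant for exact closed-loop checks."""
    kwargs = dict(
        classes=dict(_DEFAULT_CLASSES),
        valence_coef=dict(_VALENCE_TRUTH_LINEAR),
        arousal_coef=dict(_AROUSAL_TRUTH),
        rating_noise_sd=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def _poly_eval(coefs: dict, g, td):
    g = np.asarray(g, dtype=float)
    td = np.asarray(td, dtype=float)
    out = np.zeros(np.broadcast(g, td).shape)
    for (eg, et), c in coefs.items():
        out += c * g ** eg * td ** et
    return out


def _truncated_normal(rng, mean, sd, size, floor=1e-3):
    """Normal draws redrawn until strictly above ``floor`` (positivity)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out <= floor
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, floor, None)


def _draw_class_params(rng, config: GeneratorConfig):
    """Per-row SCR parameter draws for every class, clustered by class."""
    classes = config.classes or dict(_DEFAULT_CLASSES)
    rows = []
    for cls, spec in classes.items():
        n = config.n_per_class
        rows.append(pd.DataFrame({
            "affect_class": cls,
            "onset_time": _truncated_normal(rng, *spec.onset_time, n),
            "gain": _truncated_normal(rng, *spec.gain, n),
            "rise_time": _truncated_normal(rng, *spec.rise_time, n),
            "decay_time_constant":
                _truncated_normal(rng, *spec.decay_time_constant, n),
        }))
    return pd.concat(rows, ignore_index=True)


def generate_feature_table(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a per-stimulus feature table with known ground-truth ratings."""
    rng = np.random.default_rng(config.seed)
    if config.n_per_class == 0:
        return pd.DataFrame({c: pd.Series(dtype=object if c in
                                          ("stimulus_id", "affect_class",
                                           "provenance") else float)
                             for c in FEATURE_SCHEMA})
    df = _draw_class_params(rng, config)
    df.insert(0, "stimulus_id",
              [f"{cls}_{i % config.n_per_class + 1}"
               for i, cls in enumerate(df["affect_class"])])
    for target, coefs in (("valence", config.valence_coef),
                          ("arousal", config.arousal_coef)):
        clean = _poly_eval(coefs, df["gain"], df["decay_time_constant"])
        noisy = clean + rng.normal(0.0, config.rating_noise_sd, size=len(df))
        df[target] = np.clip(noisy, 1.0, 9.0) if config.clip_ratings else noisy
    df["provenance"] = "synthetic"
    return df[list(FEATURE_SCHEMA)]


def generate_sc_traces(config: GeneratorConfig):
    """Synthesize noisy post-stimulus segments with their true parameters.

    Returns a list of ``(SCTrace, SCParams)`` pairs, one per stimulus
    (n_per_class per class), each trace being the six-parameter SC model
    evaluated on the configured time grid plus Gaussian sensor noise.
    """
    rng = np.random.default_rng(config.seed)
    df = _draw_class_params(rng, config)
    n_samples = int(round(config.segment_length * config.sampling_rate))
    times = np.arange(n_samples) / config.sampling_rate
    out = []
    for _, row in df.iterrows():
        truth = SCParams(
            scr=SCRParams(g=float(row["gain"]), T_os=float(row["onset_time"]),
                          t_r=float(row["rise_time"]),
                          t_d=float(row["decay_time_constant"])),
            a0=float(rng.uniform(*config.a0_range)),
            c=float(rng.uniform(*config.c_range)),
        )
        values = sc_waveform(truth, times)
        if config.trace_noise_sd > 0:
            values = values + rng.normal(0.0, config.trace_noise_sd,
                                         size=n_samples)
        out.append((SCTrace(times=times.copy(), values=values,
                            sampling_rate=config.sampling_rate), truth))
    return out
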