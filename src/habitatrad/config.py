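"""Run configuration: one YAML-serializable object covering every stage.

Every random operation in a run traces back to seeds recorded here
(``seed`` is the root; stage seeds derive from it). The object
round-trips through YAML unchanged, which the pipeline relies on for
its manifest hashes.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


def _d(**kw):
    return field(default_factory=lambda: dict(kw))


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"

    cohort: dict = _d(
        n_samples=60,
        mutant_fraction=0.638,
        effect_size_d=1.5,
        noise_sd=20.0,
    )
    preprocess: dict = _d(clip_lo_hu=-800.0, clip_hi_hu=800.0, target_spacing_mm=1.0)
    regions: dict = _d(shell_radii_mm=[1.0, 3.0, 5.0], k=3)
    features: dict = _d(bin_width_hu=25.0, log_sigmas_mm=[1.0, 3.0], wavelet="coif1")
    selection: dict = _d(
        icc=True, icc_threshold=0.85, alpha=0.05, r_threshold=0.9, mrmr_k=30, lasso_folds=5
    )
    models: dict = _d(
        algorithms={"intra": "lightgbm", "peri1": "svm", "peri3": "extratrees",
                    "peri5": "rf", "habitat": "svm"},
        cv_folds=5,
        train_fraction=0.7,
        dtl=True,
    )

    # ------------------------------------------------------------- io
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(value, dict):
                merged = dict(default)
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
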