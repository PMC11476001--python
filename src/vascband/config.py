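"""Run configuration: every fixed constant of the analysis in one place."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields


@dataclass
class RunConfig:
    """All knobs of the end-to-end analysis; serializes losslessly to JSON.

    Defaults encode the analysis constants: 5/10/15 mm cumulative bands,
    10-fold CV on the full cohort and 5-fold on the 8-20 mm subset, VIF
    threshold 5.0, classification threshold 0.5, significance level 0.05,
    linear SVM C = 1.0, MLP with one hidden layer of 100 units and constant
    learning rate 0.001.
    """

    seed: int = 0
    bands: tuple[float, ...] = (5.0, 10.0, 15.0)
    folds_full: int = 10
    folds_subset: int = 5
    vif_threshold: float = 5.0
    classification_threshold: float = 0.5
    significance_level: float = 0.05
    svm_C: float = 1.0
    mlp_hidden_units: int = 100
    mlp_learning_rate: float = 0.001
    n_malignant: int = 69
    n_benign: int = 79
    cohort_correlation: float = 0.3
    zscore_ddof: int = 1  # sample-SD convention
    lasso_n_penalties: int = 30
    pi_repeats: int = 50
    shap_samples: int = 32
    families: list[str] | None = None

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "RunConfig":
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                payload = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in payload:
            payload["bands"] = tuple(payload["bands"])
        return cls(**payload)
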