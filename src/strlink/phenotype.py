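"""Three-class eye-colour prediction and probability-threshold grouping.

The model is the standard two-logit multinomial used by 6-SNP eye-colour
panels: with brown as the reference class,

    eta_blue = alpha_b + sum_s beta_bs * x_s
    eta_int  = alpha_i + sum_s beta_is * x_s
    (p_blue, p_int, p_brown) = softmax(eta_blue, eta_int, 0)

where x_s is the effect-allele count (0/1/2) at SNP s.  Coefficient
values are supplied via a YAML parameter file — the package ships a
synthetic demonstration set, not published estimates.

Individuals are assigned to the ``blue`` or ``brown`` group when the
corresponding class probability is >= the threshold (default 0.8);
everyone else, including confident intermediate predictions, is left
``unassigned``.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass
from typing import Optional

import yaml

from .data_model import GenotypeTable, StrlinkError

logger = logging.getLogger("strlink")

GROUP_BLUE = "blue"
GROUP_BROWN = "brown"
GROUP_UNASSIGNED = "unassigned"

N_MODEL_SNPS = 6


class ModelError(StrlinkError):
    pass


class DataError(StrlinkError):
    pass


@dataclass(frozen=True)
class ModelSnp:
    name: str
    effect_allele: str
    other_allele: str


@dataclass
class PredictionModel:
    """Two-logit multinomial model over a 6-SNP panel."""

    snps: list[ModelSnp]
    blue_intercept: float
    blue_slopes: dict[str, float]
    int_intercept: float
    int_slopes: dict[str, float]

    def __post_init__(self):
        if len(self.snps) != N_MODEL_SNPS:
            raise ModelError(f"model must have exactly {N_MODEL_SNPS} SNPs")
        names = {s.name for s in self.snps}
        if len(names) != N_MODEL_SNPS:
            raise ModelError("duplicate SNP in model")
        for s in self.snps:
            if s.effect_allele == s.other_allele:
                raise ModelError(f"{s.name}: effect allele equals other allele")
        for slopes in (self.blue_slopes, self.int_slopes):
            unknown = set(slopes) - names
            if unknown:
                raise ModelError(f"slopes for unknown SNPs: {sorted(unknown)}")


def load_model(path) -> PredictionModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)


def load_demo_model() -> PredictionModel:
    """The packaged synthetic demonstration model."""
    ref = importlib.resources.files("strlink").joinpath("data", "irisplex_demo.yaml")
    with ref.open("r") as fh:
        return model_from_dict(yaml.safe_load(fh))


def model_from_dict(doc: dict) -> PredictionModel:
    snps = [
        ModelSnp(
            name=e["name"],
            effect_allele=str(e["effect_allele"]),
            other_allele=str(e["other_allele"]),
        )
        for e in doc["snps"]
    ]
    return PredictionModel(
        snps=snps,
        blue_intercept=float(doc["blue"]["intercept"]),
        blue_slopes={k: float(v) for k, v in doc["blue"].get("slopes", {}).items()},
        int_intercept=float(doc["intermediate"]["intercept"]),
        int_slopes={k: float(v) for k, v in doc["intermediate"].get("slopes", {}).items()},
    )


@dataclass(frozen=True)
class EyeColourPrediction:
    sample_id: str
    p_blue: float
    p_intermediate: float
    p_brown: float
    group: str = GROUP_UNASSIGNED

    def __post_init__(self):
        total = self.p_blue + self.p_intermediate + self.p_brown
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ModelError(f"probabilities sum to {total}, not 1")


def class_probabilities(
    eta_blue: float, eta_int: float, eta_brown: float = 0.0
) -> tuple[float, float, float]:
    """Softmax over the three class scores (brown's is 0 in the model)."""
    m = max(eta_blue, eta_int, eta_brown)
    eb = math.exp(eta_blue - m)
    ei = math.exp(eta_int - m)
    er = math.exp(eta_brown - m)
    z = eb + ei + er
    return eb / z, ei / z, er / z


def _effect_allele_count(call, snp: ModelSnp, sample_id: str) -> int:
    count = 0
    for a in call:
        if a == snp.effect_allele:
            count += 1
        elif a != snp.other_allele:
            raise DataError(
                f"sample {sample_id!r}, SNP {snp.name}: allele {a!r} matches "
                f"neither {snp.effect_allele!r} nor {snp.other_allele!r}"
            )
    return count


def predict(gt: GenotypeTable, model: PredictionModel) -> list[Optional[EyeColourPrediction]]:
    """Per-sample class probabilities; None for samples missing a model SNP.

    Probabilities come from the softmax of the two linear predictors with
    the brown logit fixed at zero.
    """
    for s in model.snps:
        if s.name not in gt.calls:
            raise ModelError(f"model SNP {s.name} absent from genotype table")
    preds: list[Optional[EyeColourPrediction]] = []
    n_skipped = 0
    for i in range(gt.n_samples):
        sample_id = gt.samples["sample_id"].iloc[i]
        calls = {s.name: gt.calls[s.name][i] for s in model.snps}
        if any(c is None for c in calls.values()):
            n_skipped += 1
            preds.append(None)
            continue
        eta_blue = model.blue_intercept
        eta_int = model.int_intercept
        for s in model.snps:
            x = _effect_allele_count(calls[s.name], s, sample_id)
            eta_blue += model.blue_slopes.get(s.name, 0.0) * x
            eta_int += model.int_slopes.get(s.name, 0.0) * x
        p_blue, p_int, p_brown = class_probabilities(eta_blue, eta_int)
        preds.append(
            EyeColourPrediction(
                sample_id=sample_id,
                p_blue=p_blue,
                p_intermediate=p_int,
                p_brown=p_brown,
            )
        )
    if n_skipped:
        logger.warning("predict: skipped %d samples missing a model SNP", n_skipped)
    return preds


def assign_groups(
    preds: list[Optional[EyeColourPrediction]], threshold: float = 0.8
) -> list[Optional[str]]:
    """Threshold rule: blue if p_blue >= threshold, brown if p_brown >=
    threshold, else unassigned (None for unpredicted samples).

    ``threshold`` must exceed 0.5 so the two groups are exclusive.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    labels: list[Optional[str]] = []
    for p in preds:
        if p is None:
            labels.append(None)
        elif p.p_blue >= threshold:
            labels.append(GROUP_BLUE)
        elif p.p_brown >= threshold:
            labels.append(GROUP_BROWN)
        else:
            labels.append(GROUP_UNASSIGNED)
    counts = {
        g: sum(1 for l in labels if l == g)
        for g in (GROUP_BLUE, GROUP_BROWN, GROUP_UNASSIGNED)
    }
    logger.info("group assignment at threshold %.2f: %s", threshold, counts)
    return labels


def predict_and_group(
    gt: GenotypeTable, model: PredictionModel, threshold: float = 0.8
) -> GenotypeTable:
    """Convenience: predict, assign groups, return a labelled table."""
    preds = predict(gt, model)
    labels = assign_groups(preds, threshold)
    return gt.with_groups(
        [l if l in (GROUP_BLUE, GROUP_BROWN) else None for l in labels]
    )
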