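"""Synthetic short-term toxicogenomics datasets with planted signatures.

The generator emulates the design of the mouse-liver study the pipeline is
built for: ~14 compounds in four classes (genotoxic carcinogens, nongenotoxic
carcinogens, non-carcinogens, and undefined compounds), up to two dose groups
per compound, two sexes, two dosing durations (3 and 14 days), 6 replicate
animals per treatment group, and time-matched vehicle controls for both
vehicles.  Class-specific differential expression is planted in three
disjoint probeset sets: GC-specific, NGC-specific, and a shared carcinogen
set perturbed by every carcinogen.  Effects are attenuated at day 3 relative
to day 14, mirroring the empirical pattern that short dosing gives weaker
signal.  Undefined compounds are generated from an explicit GC-like or
NGC-like regime so their post-hoc classification has a known right answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionDataset, GroupProfile, SampleAnnotation

#: (compound, class, vehicle, doses, regime) mirroring the study's scale:
#: 3 GC compounds (one with two doses), 3 NGC, 4 NC, 3 UNDEF.
DEFAULT_COMPOUNDS = (
    ("GTXA", "GC", "CO", (2500,), None),
    ("GTXB", "GC", "CO", (2,), None),
    ("GTXC", "GC", "CO", (50, 75), None),
    ("NGTA", "NGC", "CO", (600,), None),
    ("NGTB", "NGC", "CMC", (80,), None),
    ("NGTC", "NGC", "CMC", (600,), None),
    ("NCA", "NC", "CMC", (250,), None),
    ("NCB", "NC", "CMC", (50,), None),
    ("NCC", "NC", "CMC", (5,), None),
    ("NCD", "NC", "CO", (80,), None),
    ("UNDA", "UNDEF", "CO", (160,), "NGC-like"),
    ("UNDB", "UNDEF", "CMC", (20,), "GC-like"),
    ("UNDC", "UNDEF", "CMC", (200,), "GC-like"),
)


@dataclass
class SyntheticDesign:
    """Knobs of the generative model (defaults emulate the study design)."""

    n_probesets: int = 2000
    n_gc_specific: int = 20
    n_ngc_specific: int = 20
    n_shared: int = 20
    effect_size: float = 2.0        # mean log2 shift in units of replicate_sd
    sex_effect: float = 0.5         # log2 shift in males on 5% of probesets
    sex_effect_fraction: float = 0.05
    replicate_sd: float = 0.5       # within-group log2 SD
    replicates: int = 6
    durations: tuple[int, ...] = (3, 14)
    day3_attenuation: float = 0.6   # effect multiplier at day 3 vs day 14
    compound_effect_range: tuple[float, float] = (0.8, 1.2)
    compounds: tuple = DEFAULT_COMPOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_gc_specific + self.n_ngc_specific + self.n_shared
        if planted > self.n_probesets:
            raise ValueError("planted sets exceed the number of probesets")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for name, v in (("n_probesets", self.n_probesets),
                        ("replicates", self.replicates)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery and undefined-compound calls."""

    gc_specific: list[str]
    ngc_specific: list[str]
    shared: list[str]
    sex_affected: list[str]
    compound_class: dict[str, str]
    undef_regime: dict[str, str]
    signs: dict[str, int] = field(default_factory=dict)

    def relevant_planted(self, task: str) -> set[str]:
        """Planted probesets carrying signal for a task's discrimination."""
        sets = {
            "C_vs_NC": self.shared + self.gc_specific + self.ngc_specific,
            "GC_vs_NGC": self.gc_specific + self.ngc_specific,
            "GC_vs_NC": self.gc_specific + self.shared,
            "NGC_vs_NC": self.ngc_specific + self.shared,
        }
        if task not in sets:
            raise ValueError(f"unknown task {task!r}")
        return set(sets[task])


def generate(design: SyntheticDesign | None = None) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a full synthetic dataset plus its ground truth.

    Baseline log2 expression is Normal(8, 1) per probeset; every sample adds
    Normal(0, replicate_sd) noise.  Treated samples of carcinogens add signed
    shifts of ``effect_size x replicate_sd`` on their class's planted sets,
    scaled per compound and attenuated at day 3.  Bit-reproducible for a
    fixed seed.
    """
    design = design or SyntheticDesign()
    rng = np.random.default_rng(design.seed)
    P = design.n_probesets
    probeset_ids = [f"ps{i:05d}" for i in range(P)]

    planted_idx = rng.choice(P, design.n_gc_specific + design.n_ngc_specific
                             + design.n_shared, replace=False)
    gc_idx = planted_idx[:design.n_gc_specific]
    ngc_idx = planted_idx[design.n_gc_specific:
                          design.n_gc_specific + design.n_ngc_specific]
    shared_idx = planted_idx[design.n_gc_specific + design.n_ngc_specific:]
    signs = np.zeros(P)
    signs[planted_idx] = rng.choice([-1.0, 1.0], planted_idx.size)
    n_sex = int(round(design.sex_effect_fraction * P))
    sex_idx = rng.choice(P, n_sex, replace=False)

    baseline = rng.normal(8.0, 1.0, P)
    shift_mag = design.effect_size * design.replicate_sd

    class_sets = {"GC": np.concatenate([gc_idx, shared_idx]),
                  "NGC": np.concatenate([ngc_idx, shared_idx]),
                  "NC": np.array([], dtype=int)}
    regime_of = {}
    compound_modifier = {}
    for comp, cls, _, _, regime in design.compounds:
        lo, hi = design.compound_effect_range
        compound_modifier[comp] = float(rng.uniform(lo, hi))
        if cls == "UNDEF":
            regime_of[comp] = regime

    columns, annotations = [], []

    def add_sample(sample_id, group_id, compound, vehicle, dose, sex, duration, cls,
                   effect_idx, effect_scale):
        expr = baseline + rng.normal(0.0, design.replicate_sd, P)
        if effect_idx.size:
            expr[effect_idx] += signs[effect_idx] * shift_mag * effect_scale
        if sex == "M":
            expr[sex_idx] += design.sex_effect
        columns.append(expr)
        annotations.append(SampleAnnotation(
            sample_id=sample_id, group_id=group_id, compound=compound,
            vehicle=vehicle, dose=float(dose), sex=sex, duration_days=duration,
            class_label=cls))

    for duration in design.durations:
        atten = design.day3_attenuation if duration == 3 else 1.0
        dtag = f"D{duration}"
        for vehicle in ("CO", "CMC"):
            for sex in ("M", "F"):
                gid = f"CTRL_{vehicle}_{sex}_{dtag}"
                for r in range(design.replicates):
                    add_sample(f"{gid}_r{r + 1}", gid, vehicle, vehicle, 0.0, sex,
                               duration, "CONTROL", np.array([], dtype=int), 0.0)
        for comp, cls, vehicle, doses, regime in design.compounds:
            if cls == "UNDEF":
                effect_idx = class_sets[regime.split("-")[0]]
            else:
                effect_idx = class_sets[cls]
            for gi, dose in enumerate(doses):
                for sex in ("M", "F"):
                    gid = f"{comp}_G{gi + 1}{sex}_{dtag}"
                    scale = atten * compound_modifier[comp]
                    for r in range(design.replicates):
                        add_sample(f"{gid}_r{r + 1}", gid, comp, vehicle, dose,
                                   sex, duration, cls, effect_idx, scale)

    ds = ExpressionDataset(
        values=np.column_stack(columns), probeset_ids=probeset_ids,
        sample_ids=[a.sample_id for a in annotations], annotations=annotations)
    truth = GroundTruth(
        gc_specific=[probeset_ids[i] for i in np.sort(gc_idx)],
        ngc_specific=[probeset_ids[i] for i in np.sort(ngc_idx)],
        shared=[probeset_ids[i] for i in np.sort(shared_idx)],
        sex_affected=[probeset_ids[i] for i in np.sort(sex_idx)],
        compound_class={c: cls for c, cls, _, _, _ in design.compounds},
        undef_regime=dict(regime_of),
        signs={probeset_ids[i]: int(signs[i]) for i in planted_idx},
    )
    return ds, truth


def recovery_score(consensus, truth: GroundTruth, task: str) -> float:
    """Fraction of the signature's capacity filled with task-relevant planted
    probesets: |consensus ∩ relevant| / min(|consensus|, |relevant|).

    Equals 1 when the signature is drawn entirely from the planted features
    (or contains all of them) and 0 when it misses them completely.
    """
    ids = consensus.probeset_ids if hasattr(consensus, "probeset_ids") else list(consensus)
    if not ids:
        raise ValueError("empty consensus signature")
    relevant = truth.relevant_planted(task)
    return len(set(ids) & relevant) / min(len(ids), len(relevant))


def write_tables(ds: ExpressionDataset, truth: GroundTruth, out_dir) -> dict[str, str]:
    """Emit the tab-delimited expression/annotation/ground-truth tables."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_path = out / "expression.tsv"
    pd.DataFrame(ds.values, index=pd.Index(ds.probeset_ids, name="probeset_id"),
                 columns=ds.sample_ids).to_csv(expr_path, sep="\t")
    ann_path = out / "annotations.tsv"
    pd.DataFrame([{
        "sample_id": a.sample_id, "group_id": a.group_id, "compound": a.compound,
        "vehicle": a.vehicle, "dose": a.dose, "sex": a.sex,
        "duration": a.duration_days, "class": a.class_label,
    } for a in ds.annotations]).to_csv(ann_path, sep="\t", index=False)
    truth_path = out / "ground_truth.tsv"
    rows = ([{"probeset_id": p, "role": "gc_specific", "sign": truth.signs[p]}
             for p in truth.gc_specific]
            + [{"probeset_id": p, "role": "ngc_specific", "sign": truth.signs[p]}
               for p in truth.ngc_specific]
            + [{"probeset_id": p, "role": "shared", "sign": truth.signs[p]}
               for p in truth.shared])
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
    return {"expression": str(expr_path), "annotations": str(ann_path),
            "ground_truth": str(truth_path)}
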