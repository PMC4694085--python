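"""Synthetic item-method directed-forgetting experiments.

This module generates complete trial tables with the generative structure
the downstream analyses assume: study items cued Remember (R) or Forget (F),
speeded probe-detection RTs (log-normal per instruction x task), old/new or
remember/know/no recognition responses (multilevel logistic), and continuous
color-report errors drawn from a two-component mixture -- a von Mises
"memory" component whose concentration may vary from trial to trial, and a
uniform "guessing" component.

Four built-in designs mirror the four experiments the package targets:

* ``e1``  -- 20 participants, 15 R / 15 F / 30 foils, probes on ~75% of study
  trials, old/new recognition, no color judgment.
* ``e2``  -- 24 participants, adds the color wheel and baseline RT blocks.
* ``e3``  -- 36 participants, remember/know/no recognition.
* ``e4``  -- 33 participants, 60 R / 60 F, color judgment only (no probes,
  no foils, no recognition report).

Between-participant heterogeneity (random-intercept SDs) is required by the
multilevel analyses but is not published; the defaults encode moderate,
recoverable heterogeneity and are documented in the methods note.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .circular import sample_von_mises, sigma_to_kappa, signed_error, wrap_angle

__all__ = [
    "ExperimentDesign", "GenParams", "Dataset", "SchemaError",
    "experiment_design", "trial_schedule_total",
    "generate_experiment", "write_dataset", "read_dataset",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant", "phase", "trial_index", "item_id", "item_type",
    "probe_present", "probe_rt_ms", "recognition_response",
    "recognition_rt_ms", "studied_color", "response_color",
    "signed_error", "color_rt_ms",
]


class SchemaError(ValueError):
    """A trial table violates the expected schema."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Counts, protocol, and study-trial event schedule for one experiment."""

    name: str
    n_participants: int
    n_R: int
    n_F: int
    n_foil: int
    probe_fraction: float
    response_protocol: str  # old_new | remember_know_no | color_only
    has_color_judgment: bool
    has_baseline_blocks: bool
    event_durations_ms: tuple = ()
    stated_total_ms: float | None = None

    def __post_init__(self):
        if min(self.n_R, self.n_F, self.n_foil, self.n_participants) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.probe_fraction <= 1.0:
            raise ValueError("probe_fraction must be in [0, 1]")
        if self.response_protocol not in ("old_new", "remember_know_no", "color_only"):
            raise ValueError(f"unknown protocol {self.response_protocol!r}")
        if self.response_protocol == "color_only" and (
                self.probe_fraction != 0 or self.n_foil != 0):
            raise ValueError("color_only designs have no probes and no foils")


# Study-trial event schedules.  The probe-task experiments enumerate
# fixation 1500, blank 800, item 1000, blank 500, tone 400, blank 600,
# probe 600, blank 2000 (the stated 7,800 ms total exceeds this sum by
# 400 ms; see trial_schedule_total).  The color-only design runs
# fixation 1500, blank 800, item 2000, blank 500, tone 400, ITI 1600.
_E13_EVENTS = (("fixation", 1500), ("blank", 800), ("item", 1000),
               ("blank2", 500), ("tone", 400), ("blank3", 600),
               ("probe", 600), ("blank4", 2000))
_E4_EVENTS = (("fixation", 1500), ("blank", 800), ("item", 2000),
              ("blank2", 500), ("tone", 400), ("iti", 1600))

_DESIGNS = {
    "e1": ExperimentDesign("e1", 20, 15, 15, 30, 11 / 15, "old_new",
                           False, False, _E13_EVENTS, stated_total_ms=7800),
    "e2": ExperimentDesign("e2", 24, 15, 15, 30, 11 / 15, "old_new",
                           True, True, _E13_EVENTS, stated_total_ms=7800),
    "e3": ExperimentDesign("e3", 36, 15, 15, 30, 11 / 15, "remember_know_no",
                           True, True, _E13_EVENTS, stated_total_ms=7800),
    "e4": ExperimentDesign("e4", 33, 60, 60, 0, 0.0, "color_only",
                           True, False, _E4_EVENTS, stated_total_ms=6800),
}


def experiment_design(name: str, **overrides) -> ExperimentDesign:
    """Return a built-in design (``e1``..``e4``), optionally overridden."""
    try:
        base = _DESIGNS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown design {name!r}; choose from {sorted(_DESIGNS)}")
    if overrides:
        d = asdict(base)
        d.update(overrides)
        d["event_durations_ms"] = tuple(map(tuple, d["event_durations_ms"]))
        return ExperimentDesign(**d)
    return base


def trial_schedule_total(design: ExperimentDesign) -> float:
    """Sum of the study-trial event durations in ms.

    If the design also records a stated total that disagrees with the
    component sum, a warning flags the discrepancy (the component sum is
    returned either way, rather than guessing at the missing time).
    """
    durations = [ms for _, ms in design.event_durations_ms]
    if any(ms < 0 for ms in durations):
        raise ValueError("event durations must be >= 0")
    total = float(sum(durations))
    if design.stated_total_ms is not None and design.stated_total_ms != total:
        warnings.warn(
            f"design {design.name!r}: stated trial duration "
            f"{design.stated_total_ms} ms differs from the component sum "
            f"{total} ms", RuntimeWarning, stacklevel=2)
    return total


@dataclass
class GenParams:
    """Generative truth for a simulated experiment.

    ``rho_*`` are group-level retrieval probabilities, ``sigma_*_deg`` the
    corresponding memory fidelities (circular SD of the von Mises memory
    component, degrees).  ``vp_spread`` is the SD of trial-level log
    concentration (0 = fixed precision).  Logistic coefficient triples are
    ``(intercept_foil, slope_F, slope_R)`` on the logit scale.  ``rt_log_*``
    parameterize log-normal probe RTs per (instruction, task) cell.
    ``ranef_sd_*`` are between-participant random-intercept SDs.
    """

    rho_R: float = 0.65
    rho_F: float = 0.51
    sigma_R_deg: float = 30.24
    sigma_F_deg: float = 38.73
    vp_spread: float = 0.4
    logit_coefs: tuple = (-0.39, 0.43, 0.97)
    remember_coefs: tuple = (-1.93, 0.64, 1.02)
    know_coefs: tuple = (0.32, 0.61, 0.62)
    rt_log_means: dict = field(default_factory=lambda: {
        ("F", "study"): 6.32, ("R", "study"): 6.18,
        ("F", "control"): 6.11, ("R", "control"): 6.09,
    })
    rt_log_sd: float = 0.25
    recog_rt_log_mean: float = 6.9
    recog_rt_log_sd: float = 0.35
    color_rt_log_mean: float = 8.40
    color_rt_log_sd: float = 0.30
    ranef_sd_logit: float = 0.5
    ranef_sd_rho: float = 0.5
    ranef_sd_logkappa: float = 0.25
    ranef_sd_rt: float = 0.15
    seed: int | None = None

    def __post_init__(self):
        for name in ("rho_R", "rho_F"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("sigma_R_deg", "sigma_F_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("vp_spread", "rt_log_sd", "ranef_sd_logit",
                     "ranef_sd_rho", "ranef_sd_logkappa", "ranef_sd_rt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rho(self, cond: str) -> float:
        return {"R": self.rho_R, "F": self.rho_F}[cond]

    def kappa(self, cond: str) -> float:
        return sigma_to_kappa({"R": self.sigma_R_deg, "F": self.sigma_F_deg}[cond])

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["rt_log_means"] = {f"{i}:{t}": v for (i, t), v in self.rt_log_means.items()}
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "GenParams":
        d = dict(d)
        d["rt_log_means"] = {tuple(k.split(":")): v
                             for k, v in d["rt_log_means"].items()}
        d["logit_coefs"] = tuple(d["logit_coefs"])
        d["remember_coefs"] = tuple(d["remember_coefs"])
        d["know_coefs"] = tuple(d["know_coefs"])
        return cls(**d)


@dataclass
class Dataset:
    """A trial table together with its design and (if simulated) its truth."""

    design: ExperimentDesign
    truth: GenParams | None
    records: pd.DataFrame

    def study(self) -> pd.DataFrame:
        return self.records[self.records.phase == "study"]

    def test(self) -> pd.DataFrame:
        return self.records[self.records.phase == "test"]


def _logistic_p(coefs, item_type, u):
    icpt, bF, bR = coefs
    x = icpt + (bF if item_type == "F" else 0.0) + (bR if item_type == "R" else 0.0)
    return expit(x + u)


def generate_experiment(design, params: GenParams | None = None,
                        seed: int | None = None) -> Dataset:
    """Simulate a full experiment under ``design`` with truth ``params``.

    Deterministic given the seed (``seed`` argument wins over
    ``params.seed``).  Color-report errors for studied items follow the
    mixture generative model: with participant-level probability
    ``expit(logit(rho_cond) + u_p)`` the signed error is von Mises with
    trial concentration ``exp(log kappa_cond + v_p + vp_spread * z_t)``;
    otherwise it is uniform on the wheel.  Foils are never studied, so their
    color selections are uniform and carry no error.
    """
    params = params or GenParams()
    if design.response_protocol == "remember_know_no" and (
            params.remember_coefs is None or params.know_coefs is None):
        raise ValueError("remember_know_no designs need remember_coefs and know_coefs")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    kappa_cond = {c: params.kappa(c) for c in ("R", "F")}
    rows = []
    n_study = design.n_R + design.n_F
    for p in range(1, design.n_participants + 1):
        u_recog = rng.normal(0, params.ranef_sd_logit)
        u_rem = rng.normal(0, params.ranef_sd_logit)
        u_know = rng.normal(0, params.ranef_sd_logit)
        u_rho = rng.normal(0, params.ranef_sd_rho)
        u_lk = rng.normal(0, params.ranef_sd_logkappa)
        u_rt = rng.normal(0, params.ranef_sd_rt)

        # equally spaced study colors with a random per-participant rotation
        colors = wrap_angle(np.arange(n_study) * (360.0 / max(n_study, 1))
                            + rng.uniform(0, 360))
        rng.shuffle(colors)
        item_types = np.array(["R"] * design.n_R + ["F"] * design.n_F)
        rng.shuffle(item_types)
        studied_color = dict(zip(range(n_study), colors))

        # probe assignment: round(probe_fraction * n) probes per instruction
        probe_flags = {}
        for cond, n_cond in (("R", design.n_R), ("F", design.n_F)):
            idx = np.where(item_types == cond)[0]
            n_probe = int(round(design.probe_fraction * n_cond))
            chosen = rng.choice(idx, size=n_probe, replace=False) if n_probe else []
            for i in idx:
                probe_flags[i] = i in set(np.atleast_1d(chosen))

        def blank_row(phase, trial_index, item_id, item_type):
            return {
                "participant": p, "phase": phase, "trial_index": trial_index,
                "item_id": item_id, "item_type": item_type,
                "probe_present": False, "probe_rt_ms": np.nan,
                "recognition_response": "none", "recognition_rt_ms": np.nan,
                "studied_color": np.nan, "response_color": np.nan,
                "signed_error": np.nan, "color_rt_ms": np.nan,
            }

        def draw_rt(instruction, task):
            mu = params.rt_log_means[(instruction, task)] + u_rt
            return float(np.exp(rng.normal(mu, params.rt_log_sd)))

        # -- baseline blocks (probe task without a memory task) --
        if design.has_baseline_blocks:
            t = 0
            for _block in range(2):
                block = (["R", True] * 4 + ["F", True] * 4
                         + ["R", False] * 2 + ["F", False] * 2)
                conds = np.array(block[0::2], dtype=object)
                probes = np.array(block[1::2], dtype=bool)
                order = rng.permutation(len(conds))
                for i in order:
                    t += 1
                    row = blank_row("baseline", t, f"baseline-{t}", conds[i])
                    row["probe_present"] = bool(probes[i])
                    if probes[i]:
                        row["probe_rt_ms"] = draw_rt(conds[i], "control")
                    rows.append(row)

        # -- study phase --
        for t, i in enumerate(rng.permutation(n_study), start=1):
            cond = item_types[i]
            row = blank_row("study", t, f"item-{i}", cond)
            row["studied_color"] = studied_color[i] if design.has_color_judgment else np.nan
            row["probe_present"] = bool(probe_flags.get(i, False))
            if row["probe_present"]:
                row["probe_rt_ms"] = draw_rt(cond, "study")
            rows.append(row)

        # -- test phase --
        test_items = [(f"item-{i}", item_types[i]) for i in range(n_study)]
        test_items += [(f"foil-{j}", "foil") for j in range(design.n_foil)]
        order = rng.permutation(len(test_items))
        rho_p = {c: float(expit(logit(params.rho(c)) + u_rho)) for c in ("R", "F")}
        logkappa_p = {c: float(np.log(kappa_cond[c]) + u_lk) for c in ("R", "F")}
        for t, j in enumerate(order, start=1):
            item_id, cond = test_items[j]
            row = blank_row("test", t, item_id, cond)
            # recognition report
            if design.response_protocol == "old_new":
                p_old = _logistic_p(params.logit_coefs, cond, u_recog)
                row["recognition_response"] = "old" if rng.random() < p_old else "new"
                row["recognition_rt_ms"] = float(np.exp(rng.normal(
                    params.recog_rt_log_mean + u_rt, params.recog_rt_log_sd)))
            elif design.response_protocol == "remember_know_no":
                p_rem = _logistic_p(params.remember_coefs, cond, u_rem)
                if rng.random() < p_rem:
                    row["recognition_response"] = "remember"
                else:
                    p_know = _logistic_p(params.know_coefs, cond, u_know)
                    row["recognition_response"] = "know" if rng.random() < p_know else "no"
                row["recognition_rt_ms"] = float(np.exp(rng.normal(
                    params.recog_rt_log_mean + u_rt, params.recog_rt_log_sd)))
            # color report
            if design.has_color_judgment:
                if cond == "foil":
                    row["response_color"] = float(rng.uniform(0, 360))
                else:
                    idx = int(item_id.split("-")[1])
                    sc = studied_color[idx]
                    if rng.random() < rho_p[cond]:
                        lk = logkappa_p[cond]
                        if params.vp_spread > 0:
                            lk = lk + params.vp_spread * rng.standard_normal()
                        err = float(sample_von_mises(np.exp(lk), 1, rng)[0])
                    else:
                        err = float(180.0 - rng.uniform(0, 360))
                    row["studied_color"] = sc
                    row["response_color"] = float(wrap_angle(sc + err))
                    row["signed_error"] = float(signed_error(sc, row["response_color"]))
                row["color_rt_ms"] = float(np.exp(rng.normal(
                    params.color_rt_log_mean + u_rt, params.color_rt_log_sd)))
            rows.append(row)

    records = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return Dataset(design=design, truth=params, records=records)


# ---------------------------------------------------------------------------
# CSV round trip

def write_dataset(ds: Dataset, path) -> None:
    """Write the trial table to ``path`` (CSV) with a JSON sidecar.

    The sidecar ``<path>.meta.json`` stores the design and, for simulated
    data, the generative truth.
    """
    path = Path(path)
    ds.records.to_csv(path, index=False, float_format="%.8f")
    meta = {"design": asdict(ds.design)}
    meta["design"]["event_durations_ms"] = [list(e) for e in ds.design.event_durations_ms]
    if ds.truth is not None:
        meta["truth"] = ds.truth.to_json_dict()
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing column(s): {missing}")
    for col in ("studied_color", "response_color"):
        vals = df[col].dropna()
        if len(vals) and ((vals < 0).any() or (vals >= 360).any()):
            raise SchemaError(f"column {col!r} has angles outside [0, 360)")
    err = df["signed_error"].dropna()
    if len(err) and ((err <= -180).any() or (err > 180).any()):
        raise SchemaError("column 'signed_error' has values outside (-180, 180]")
    bad = set(df["item_type"].dropna()) - {"R", "F", "foil"}
    if bad:
        raise SchemaError(f"column 'item_type' has unknown levels {sorted(bad)}")
    return df


def read_dataset(path) -> Dataset:
    """Read a trial table (and its sidecar, if present) back into a Dataset."""
    path = Path(path)
    df = pd.read_csv(path)
    _validate_records(df)
    df["probe_present"] = df["probe_present"].astype(bool)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    design, truth = None, None
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        d = meta["design"]
        d["event_durations_ms"] = tuple(tuple(e) for e in d["event_durations_ms"])
        design = ExperimentDesign(**d)
        if "truth" in meta:
            truth = GenParams.from_json_dict(meta["truth"])
    if design is None:
        # minimal design inferred from the table
        n_p = df["participant"].nunique()
        test = df[df.phase == "test"]
        has_recog = (test["recognition_response"] != "none").any()
        has_color = bool(test["response_color"].notna().any())
        per = test.groupby("item_type").size() // max(n_p, 1)
        n_foil = int(per.get("foil", 0))
        design = ExperimentDesign(
            name="csv", n_participants=n_p,
            n_R=int(per.get("R", 0)), n_F=int(per.get("F", 0)),
            n_foil=n_foil if has_recog else 0, probe_fraction=0.0,
            response_protocol="old_new" if has_recog else "color_only",
            has_color_judgment=has_color,
            has_baseline_blocks=bool((df.phase == "baseline").any()),
        )
    return Dataset(design=design, truth=truth, records=df)
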