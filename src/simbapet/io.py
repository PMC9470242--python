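"""Study dataset container and tabular text readers/writers.

A study directory holds:

* ``tacs.tsv``        subject, region, frame_start, frame_end, value
* ``covariates.tsv``  subject, group, (age, sex, ...)
* ``aif_params.tsv``  one fitted/known AIF per subject, or
* ``blood.tsv``       subject, time_min, concentration, kind
* ``wb_means.tsv``    per-subject whole-blood frame means (optional; derived
                      from blood or AIF when absent)
* ``truth.json``      simulation ground truth (optional)

All files are UTF-8 TSV with floats at 6 significant digits so repeated
writes are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blood import AIFParameters, BloodSamples, aif_frame_means, whole_blood_frame_means
from .kinetics import FrameSchedule

__all__ = ["StudyDataset", "read_study", "write_study"]

AIF_COLS = ["t0", "b", "tp", "A1", "A2", "A3", "lambda1", "lambda2", "lambda3"]


@dataclass
class StudyDataset:
    """All TACs, blood descriptions, frame schedule and covariates for one study."""

    tacs: pd.DataFrame
    covariates: pd.DataFrame
    schedule: FrameSchedule
    aifs: dict | None = None
    blood: dict | None = None
    wb_means: dict = field(default_factory=dict)
    truth: dict | None = None
    missing_frames: list = field(default_factory=list)

    def __post_init__(self):
        req = {"subject", "region", "frame_start", "frame_end", "value"}
        if not req.issubset(self.tacs.columns):
            raise ValueError(f"tacs table must have columns {sorted(req)}")
        if "subject" not in self.covariates.columns:
            raise ValueError("covariates table must have a 'subject' column")
        tac_subjects = set(self.tacs["subject"].astype(str))
        cov_subjects = set(self.covariates["subject"].astype(str))
        missing = sorted(tac_subjects - cov_subjects)
        if missing:
            raise ValueError(f"subjects missing from covariates table: {missing}")
        self._check_frames()
        if self.aifs is None and self.blood is None:
            raise ValueError("study requires per-subject AIF parameters or blood samples")
        if not self.wb_means:
            self.wb_means = {s: self.subject_wb_means(s) for s in sorted(tac_subjects)}

    def _check_frames(self):
        full = list(zip(self.schedule.start, self.schedule.end))
        self.missing_frames = []
        for (subj, reg), g in self.tacs.groupby(["subject", "region"], sort=False):
            starts = g["frame_start"].to_numpy(float)
            ends = g["frame_end"].to_numpy(float)
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            if np.any(starts[1:] < ends[:-1] - 1e-9):
                raise ValueError(f"overlapping frames for TAC ({subj}, {reg})")
            have = {(round(a, 6), round(b, 6)) for a, b in zip(starts, ends)}
            for a, b in full:
                key = (round(a, 6), round(b, 6))
                if key not in have:
                    self.missing_frames.append((str(subj), str(reg), float(a), float(b)))

    def subject_wb_means(self, subject: str) -> np.ndarray:
        if self.wb_means and subject in self.wb_means:
            return self.wb_means[subject]
        if self.blood is not None and subject in self.blood:
            wb = self.blood[subject]
            return whole_blood_frame_means(wb, self.schedule)
        if self.aifs is not None and subject in self.aifs:
            # whole blood taken as the plasma curve (constant blood:plasma ratio)
            return aif_frame_means(self.aifs[subject], self.schedule)
        raise KeyError(f"no blood information for subject {subject}")

    @property
    def subjects(self) -> list:
        return sorted(set(self.covariates["subject"].astype(str)))

    @property
    def regions(self) -> list:
        return sorted(set(self.tacs["region"].astype(str)))

    @property
    def n_tacs(self) -> int:
        return len(self.tacs.groupby(["subject", "region"]))


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: f"{v:.6g}")
    return out


def write_study(study: StudyDataset, path) -> None:
    """Write a study directory (deterministic column/row order)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tacs = study.tacs.sort_values(["subject", "region", "frame_start"]).reset_index(drop=True)
    _fmt(tacs[["subject", "region", "frame_start", "frame_end", "value"]]).to_csv(
        path / "tacs.tsv", sep="\t", index=False)
    cov = study.covariates.sort_values("subject").reset_index(drop=True)
    _fmt(cov).to_csv(path / "covariates.tsv", sep="\t", index=False)

    if study.aifs is not None:
        rows = [{"subject": s, **{c: getattr(a, c) for c in AIF_COLS}}
                for s, a in sorted(study.aifs.items())]
        _fmt(pd.DataFrame(rows)).to_csv(path / "aif_params.tsv", sep="\t", index=False)
    if study.blood is not None:
        rows = []
        for s, bs in sorted(study.blood.items()):
            for t, c in zip(bs.times, bs.concentrations):
                rows.append({"subject": s, "time_min": t, "concentration": c, "kind": bs.kind})
        _fmt(pd.DataFrame(rows)).to_csv(path / "blood.tsv", sep="\t", index=False)

    rows = []
    for s in sorted(study.wb_means):
        for a, b, v in zip(study.schedule.start, study.schedule.end, study.wb_means[s]):
            rows.append({"subject": s, "frame_start": a, "frame_end": b, "value": v})
    _fmt(pd.DataFrame(rows)).to_csv(path / "wb_means.tsv", sep="\t", index=False)

    if study.truth is not None:
        with open(path / "truth.json", "w") as fh:
            json.dump(study.truth, fh, indent=1, sort_keys=True)


def read_study(path) -> StudyDataset:
    """Read and validate a study directory written by :func:`write_study`."""
    path = Path(path)
    for fname in ("tacs.tsv", "covariates.tsv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing required file: {path / fname}")
    tacs = pd.read_csv(path / "tacs.tsv", sep="\t", dtype={"subject": str, "region": str})
    covariates = pd.read_csv(path / "covariates.tsv", sep="\t", dtype={"subject": str})

    frames = tacs[["frame_start", "frame_end"]].drop_duplicates().sort_values("frame_start")
    schedule = FrameSchedule(start=frames["frame_start"].to_numpy(float),
                             end=frames["frame_end"].to_numpy(float))

    aifs = None
    if (path / "aif_params.tsv").exists():
        df = pd.read_csv(path / "aif_params.tsv", sep="\t", dtype={"subject": str})
        aifs = {r["subject"]: AIFParameters(**{c: float(r[c]) for c in AIF_COLS})
                for _, r in df.iterrows()}
    blood = None
    if (path / "blood.tsv").exists():
        df = pd.read_csv(path / "blood.tsv", sep="\t", dtype={"subject": str})
        blood = {}
        for s, g in df.groupby("subject"):
            g = g.sort_values("time_min")
            blood[s] = BloodSamples(times=g["time_min"].to_numpy(float),
                                    concentrations=g["concentration"].to_numpy(float),
                                    kind=str(g["kind"].iloc[0]))
    if aifs is None and blood is None:
        raise FileNotFoundError(f"{path} has neither aif_params.tsv nor blood.tsv")

    wb_means = {}
    if (path / "wb_means.tsv").exists():
        df = pd.read_csv(path / "wb_means.tsv", sep="\t", dtype={"subject": str})
        for s, g in df.groupby("subject"):
            wb_means[s] = g.sort_values("frame_start")["value"].to_numpy(float)

    truth = None
    if (path / "truth.json").exists():
        with open(path / "truth.json") as fh:
            truth = json.load(fh)

    return StudyDataset(tacs=tacs, covariates=covariates, schedule=schedule,
                        aifs=aifs, blood=blood, wb_means=wb_means, truth=truth)
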