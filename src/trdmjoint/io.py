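"""Dataset container and the trial/probe CSV dialect.

One CSV holds both streams.  Columns: ``participant, trial, stimulus,
response, rt, probe_response``.  A trial row fills ``stimulus``/``response``
(and ``rt`` for go responses, in seconds with dot decimal); a probe row
leaves those empty and fills ``probe_response`` (1-4).  Trial indices are
0-based in memory and 1-based in the files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import DataIntegrityError
from .selfreport import ProbeRecord
from .trdm import TrialRecord

__all__ = ["Dataset", "read_dataset", "write_dataset", "filter_slow_trials", "FilterReport"]

COLUMNS = ["participant", "trial", "stimulus", "response", "rt", "probe_response"]

TRIAL_COLUMNS = ["participant", "trial", "stimulus", "response", "rt"]
PROBE_COLUMNS = ["participant", "trial", "response"]


@dataclass
class Dataset:
    """Trial and probe streams for any number of participants.

    ``trials``: DataFrame with columns participant, trial, stimulus
    ('go'/'nogo'), response ('go'/'withheld'), rt (float seconds, NaN when
    withheld).  ``probes``: DataFrame with columns participant, trial,
    response (int 1-4).  ``provenance`` records source path / generator seed
    and any filter reports.
    """

    trials: pd.DataFrame
    probes: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.trials = self.trials.reset_index(drop=True)
        self.probes = self.probes.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t, p = self.trials, self.probes
        if list(t.columns) != TRIAL_COLUMNS:
            raise DataIntegrityError(f"trial columns must be {TRIAL_COLUMNS}")
        if list(p.columns) != PROBE_COLUMNS:
            raise DataIntegrityError(f"probe columns must be {PROBE_COLUMNS}")
        if len(t):
            if not t["stimulus"].isin(["go", "nogo"]).all():
                raise DataIntegrityError("stimulus must be 'go' or 'nogo'")
            if not t["response"].isin(["go", "withheld"]).all():
                raise DataIntegrityError("response must be 'go' or 'withheld'")
            go = t["response"] == "go"
            if t.loc[go, "rt"].isna().any() or (t.loc[go, "rt"] <= 0).any():
                raise DataIntegrityError("go responses require rt > 0")
            if t.loc[~go, "rt"].notna().any():
                raise DataIntegrityError("withheld trials carry no rt")
            dup = t.duplicated(subset=["participant", "trial"])
            if dup.any():
                raise DataIntegrityError("trial indices must be unique per participant")
        if len(p):
            if not p["response"].isin([1, 2, 3, 4]).all():
                raise DataIntegrityError("probe responses must be in 1..4")
            extra = set(p["participant"]) - set(t["participant"]) if len(t) else set()
            if extra:
                raise DataIntegrityError(f"probe participants missing from trials: {sorted(extra)}")

    @property
    def participants(self) -> list:
        return sorted(set(self.trials["participant"]))

    def for_participant(self, pid) -> "Dataset":
        return Dataset(self.trials[self.trials["participant"] == pid],
                       self.probes[self.probes["participant"] == pid],
                       dict(self.provenance))

    def iter_trials(self) -> Iterator[TrialRecord]:
        for row in self.trials.itertuples(index=False):
            rt = None if row.response == "withheld" else float(row.rt)
            yield TrialRecord(row.participant, int(row.trial), row.stimulus, row.response, rt)

    def iter_probes(self) -> Iterator[ProbeRecord]:
        for row in self.probes.itertuples(index=False):
            yield ProbeRecord(row.participant, int(row.trial), int(row.response))

    def packed(self, participants: Optional[list] = None):
        """Flat per-participant arrays for the likelihood kernels.

        Returns (ids, rts_go_flat, go_offsets, n_withheld_go, rts_nogo_flat,
        nogo_offsets, n_withheld_nogo, probe_counts[n, 4]).
        """
        ids = participants if participants is not None else self.participants
        rts_go, rts_nogo = [], []
        go_off, nogo_off = [0], [0]
        nwh_go = np.zeros(len(ids), np.int64)
        nwh_ng = np.zeros(len(ids), np.int64)
        counts = np.zeros((len(ids), 4))
        for j, pid in enumerate(ids):
            t = self.trials[self.trials["participant"] == pid]
            go_stim = t[t["stimulus"] == "go"]
            ng_stim = t[t["stimulus"] == "nogo"]
            rts_go.append(go_stim.loc[go_stim["response"] == "go", "rt"].to_numpy(float))
            rts_nogo.append(ng_stim.loc[ng_stim["response"] == "go", "rt"].to_numpy(float))
            nwh_go[j] = int((go_stim["response"] == "withheld").sum())
            nwh_ng[j] = int((ng_stim["response"] == "withheld").sum())
            go_off.append(go_off[-1] + len(rts_go[-1]))
            nogo_off.append(nogo_off[-1] + len(rts_nogo[-1]))
            pr = self.probes[self.probes["participant"] == pid]["response"]
            for k in range(4):
                counts[j, k] = int((pr == k + 1).sum())
        cat = lambda xs: np.concatenate(xs) if xs else np.empty(0)
        return (ids, cat(rts_go), np.array(go_off, np.int64), nwh_go,
                cat(rts_nogo), np.array(nogo_off, np.int64), nwh_ng, counts)

    def content_hash(self) -> str:
        """Stable hash of the data content (used to pair fits for comparison)."""
        import hashlib
        h = hashlib.sha256()
        h.update(self.trials.to_csv(index=False).encode())
        h.update(self.probes.to_csv(index=False).encode())
        return h.hexdigest()[:16]


def read_dataset(path) -> Dataset:
    """Read the CSV dialect; malformed rows are reported with line numbers."""
    df = pd.read_csv(path, dtype={"participant": str, "stimulus": str, "response": str},
                     keep_default_na=True, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DataIntegrityError(f"missing columns: {missing}")
    trials, probes = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        is_probe = pd.notna(row["probe_response"])
        is_trial = pd.notna(row["stimulus"]) or pd.notna(row["response"])
        if is_probe and is_trial:
            raise DataIntegrityError(f"line {line}: row mixes trial and probe fields")
        if is_probe:
            resp = row["probe_response"]
            if float(resp) != int(resp) or not 1 <= int(resp) <= 4:
                raise DataIntegrityError(f"line {line}: probe_response must be an integer in 1..4")
            probes.append((row["participant"], int(row["trial"]) - 1, int(resp)))
        elif is_trial:
            stim, resp, rt = row["stimulus"], row["response"], row["rt"]
            if stim not in ("go", "nogo"):
                raise DataIntegrityError(f"line {line}: bad stimulus {stim!r}")
            if resp not in ("go", "withheld"):
                raise DataIntegrityError(f"line {line}: bad response {resp!r}")
            if resp == "go" and (pd.isna(rt) or float(rt) <= 0):
                raise DataIntegrityError(f"line {line}: go response requires rt > 0")
            if resp == "withheld" and pd.notna(rt):
                raise DataIntegrityError(f"line {line}: withheld trial carries an rt")
            trials.append((row["participant"], int(row["trial"]) - 1, stim, resp,
                           float(rt) if resp == "go" else np.nan))
        else:
            raise DataIntegrityError(f"line {line}: neither trial nor probe fields present")
    tdf = pd.DataFrame(trials, columns=TRIAL_COLUMNS)
    pdf = pd.DataFrame(probes, columns=PROBE_COLUMNS)
    return Dataset(tdf, pdf, {"source": str(path)})


def write_dataset(dataset: Dataset, path) -> None:
    """Write the CSV dialect; probe rows follow their trial's position."""
    rows = []
    for row in dataset.trials.itertuples(index=False):
        rt = "" if row.response == "withheld" else repr(float(row.rt))
        rows.append((row.participant, int(row.trial) + 1, row.stimulus, row.response, rt, ""))
    for row in dataset.probes.itertuples(index=False):
        rows.append((row.participant, int(row.trial) + 1, "", "", "", int(row.response)))
    out = pd.DataFrame(rows, columns=COLUMNS)
    out = out.sort_values(["participant", "trial"], kind="stable")
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class FilterReport:
    """Outcome of a slow-trial filter pass."""

    cutoff: float
    n_before: int
    n_removed: int

    @property
    def percent_removed(self) -> float:
        if self.n_before == 0:
            return 0.0
        return round(100.0 * self.n_removed / self.n_before, 2)


def filter_slow_trials(dataset: Dataset, cutoff: float) -> tuple[Dataset, FilterReport]:
    """Drop go-response trials slower than ``cutoff`` seconds.

    Withheld trials are never removed.  No likelihood renormalization is
    applied; slow trials are simply excluded from analysis.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    t = dataset.trials
    slow = (t["response"] == "go") & (t["rt"] > cutoff)
    report = FilterReport(cutoff, len(t), int(slow.sum()))
    prov = dict(dataset.provenance)
    prov.setdefault("filters", []).append(
        {"cutoff_s": cutoff, "removed": report.n_removed, "percent": report.percent_removed})
    return Dataset(t[~slow], dataset.probes, prov), report
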