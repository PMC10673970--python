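"""Cohort CSV I/O, temporal normalization and subject-level splitting.

The on-disk dialect is one row per (subject, echo, segment): UTF-8 CSV with
columns ``subject_id, echo_id, group, phenotype_truth, age, sex,
heart_rate_bpm, rr_ms, avc_ms, segment, followup_years, event_va,
v0..v{L-1}``; missing values are empty cells.

Temporal normalization maps every cycle onto a common 1-second axis with the
aortic-valve-closure landmark pinned at a fixed fraction (default 38%) of
the axis, via a two-segment piecewise-linear time warp: [0, AVC] stretches
onto [0, avc_frac] and [AVC, RR] onto [avc_frac, 1], then each segment curve
is linearly interpolated onto the uniform T-point grid.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import SEGMENTS, DeformationRecord, NormalizedCurveSet, RecordError

META_COLUMNS = [
    "subject_id", "echo_id", "group", "phenotype_truth", "age", "sex",
    "heart_rate_bpm", "rr_ms", "avc_ms", "segment", "followup_years", "event_va",
]


class CohortParseError(ValueError):
    """The cohort CSV could not be parsed into valid records."""


def write_cohort(records: list[DeformationRecord], path: str | Path) -> None:
    """Write records to the cohort CSV dialect (lossless float round trip)."""
    if records:
        L = records[0].n_samples
        if any(r.n_samples != L for r in records):
            raise ValueError("all records must share the same curve length")
    else:
        L = 0
    v_cols = [f"v{i}" for i in range(L)]
    rows = []
    for r in records:
        for s_idx, seg in enumerate(SEGMENTS):
            row = {
                "subject_id": r.subject_id,
                "echo_id": r.echo_id,
                "group": r.group,
                "phenotype_truth": r.phenotype_truth if r.phenotype_truth is not None else "",
                "age": r.age,
                "sex": r.sex,
                "heart_rate_bpm": r.heart_rate,
                "rr_ms": r.rr_interval,
                "avc_ms": r.avc_time,
                "segment": seg,
                "followup_years": r.followup_years if r.followup_years is not None else "",
                "event_va": {True: 1, False: 0, None: ""}[r.event_sustained_va],
            }
            row.update({c: v for c, v in zip(v_cols, r.curves[s_idx])})
            rows.append(row)
    df = pd.DataFrame(rows, columns=META_COLUMNS + v_cols)
    # %.17g guarantees a lossless float64 round trip through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path: str | Path) -> list[DeformationRecord]:
    """Read a cohort CSV, validating every record's invariants.

    Raises :class:`CohortParseError` naming the missing column or the
    offending subject.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"subject_id": str, "echo_id": str}, float_precision="round_trip"
    )
    for col in META_COLUMNS:
        if col not in df.columns:
            raise CohortParseError(f"missing mandatory column {col!r} in {path}")
    v_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    v_cols.sort(key=lambda c: int(c[1:]))
    if not v_cols and len(df):
        raise CohortParseError(f"no sample columns v0.. found in {path}")

    records: list[DeformationRecord] = []
    seen: list[tuple[str, str]] = []
    grouped: dict[tuple[str, str], list[pd.Series]] = {}
    for _, row in df.iterrows():
        key = (row["subject_id"], row["echo_id"])
        if key not in grouped:
            grouped[key] = []
            seen.append(key)
        grouped[key].append(row)

    for key in seen:
        rows = grouped[key]
        sid, eid = key
        by_seg = {r["segment"]: r for r in rows}
        missing = [s for s in SEGMENTS if s not in by_seg]
        if missing:
            raise CohortParseError(f"{sid}/{eid}: missing segments {missing}")
        first = by_seg[SEGMENTS[0]]
        curves = np.vstack(
            [by_seg[s][v_cols].to_numpy(dtype=float) for s in SEGMENTS]
        )

        def _opt_float(v):
            return None if pd.isna(v) or v == "" else float(v)

        fu = _opt_float(first["followup_years"])
        ev_raw = first["event_va"]
        ev = None if pd.isna(ev_raw) or ev_raw == "" else bool(int(ev_raw))
        pheno = first["phenotype_truth"]
        pheno = None if pd.isna(pheno) or pheno == "" else str(pheno)
        try:
            records.append(
                DeformationRecord(
                    subject_id=sid,
                    echo_id=eid,
                    group=str(first["group"]),
                    phenotype_truth=pheno,
                    age=float(first["age"]),
                    sex=str(first["sex"]),
                    heart_rate=float(first["heart_rate_bpm"]),
                    rr_interval=float(first["rr_ms"]),
                    avc_time=float(first["avc_ms"]),
                    curves=curves,
                    followup_years=fu,
                    event_sustained_va=ev,
                )
            )
        except RecordError as exc:
            raise CohortParseError(str(exc)) from exc
    return records


def normalize_time(
    record: DeformationRecord, T: int = 101, avc_frac: float = 0.38
) -> NormalizedCurveSet:
    """Warp one record onto the normalized axis with AVC pinned at avc_frac.

    ``avc_frac * (T - 1)`` must be integral so the landmark falls exactly on
    a grid index (default: index 38 of 101). Endpoint values are preserved
    and the warp is the identity when the record's AVC already sits at
    ``avc_frac`` of its RR interval.
    """
    if T < 21:
        raise ValueError("T must be >= 21")
    avc_pos = avc_frac * (T - 1)
    if abs(avc_pos - round(avc_pos)) > 1e-9:
        raise ValueError(
            f"avc_frac * (T - 1) = {avc_pos} is not integral; the AVC landmark "
            "would fall between grid indices"
        )
    avc_index = int(round(avc_pos))

    L = record.n_samples
    rr = record.rr_interval
    avc = record.avc_time
    t_in = np.linspace(0.0, rr, L)
    # insert the AVC breakpoint so the landmark value is interpolated in
    # original time, not across the warp's kink
    t_aug = np.unique(np.append(t_in, avc))
    # two-segment piecewise-linear warp of input times onto [0, 1]
    u = np.where(
        t_aug <= avc,
        avc_frac * t_aug / avc,
        avc_frac + (1.0 - avc_frac) * (t_aug - avc) / (rr - avc),
    )
    v = np.linspace(0.0, 1.0, T)
    matrix = np.vstack(
        [np.interp(v, u, np.interp(t_aug, t_in, row)) for row in record.curves]
    )
    # guard endpoints against interpolation rounding
    matrix[:, 0] = record.curves[:, 0]
    matrix[:, -1] = record.curves[:, -1]
    return NormalizedCurveSet(subject_id=record.subject_id, matrix=matrix, avc_index=avc_index)


def split_dataset(
    cohort: list[DeformationRecord], train_frac: float = 0.8, seed: int = 0
) -> tuple[list[DeformationRecord], list[DeformationRecord]]:
    """Subject-level stratified train/test split.

    Subjects never straddle the two sides. The split is stratified by group
    so the carrier proportion is preserved. On the test side only each
    subject's first echocardiogram (lexicographically smallest echo_id) is
    retained; the training side keeps all echos.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    subjects: dict[str, str] = {}
    for r in cohort:
        prev = subjects.setdefault(r.subject_id, r.group)
        if prev != r.group:
            raise ValueError(f"{r.subject_id}: inconsistent group across echos")
    by_group: dict[str, list[str]] = {"carrier": [], "control": []}
    for sid, grp in subjects.items():
        by_group[grp].append(sid)
    for grp, ids in by_group.items():
        if len(ids) < 5:
            raise ValueError(f"need >= 5 subjects per group, got {len(ids)} {grp}s")

    rng = np.random.default_rng(seed)
    train_ids: set[str] = set()
    for grp in ("carrier", "control"):
        ids = sorted(by_group[grp])
        rng.shuffle(ids)
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.update(ids[:n_train])

    train = [r for r in cohort if r.subject_id in train_ids]
    test_all = [r for r in cohort if r.subject_id not in train_ids]
    first_echo: dict[str, str] = {}
    for r in test_all:
        cur = first_echo.get(r.subject_id)
        if cur is None or r.echo_id < cur:
            first_echo[r.subject_id] = r.echo_id
    test = [r for r in test_all if r.echo_id == first_echo[r.subject_id]]
    return train, test
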