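"""Session bundle I/O.

A session is stored as a directory bundle:

    session.json          subject/area metadata + recording blocks
    episodes.csv          onset_s, offset_s, partner_id, partner_sex
    units/<unit_id>.csv   one spike time (s) per line

or, when the path ends in ``.h5``, as a single HDF5 file with the same
schema.  Reading re-validates every structural invariant; malformed bundles
raise :class:`~soctouch.session.ValidationError` rather than being silently
repaired.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import RecordingBlock, Session, TouchEpisode

__all__ = ["read_session", "write_session"]

EPISODE_COLUMNS = ["onset_s", "offset_s", "partner_id", "partner_sex"]


def write_session(session: Session, path) -> Path:
    """Write a session bundle; returns the path written."""
    path = Path(path)
    if path.suffix == ".h5":
        return _write_h5(session, path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": session.subject_id,
        "subject_sex": session.subject_sex,
        "area": session.area,
        "blocks": [
            {
                "block_index": b.block_index,
                "start": b.start,
                "end": b.end,
                "partner_ids": sorted(b.partner_ids),
            }
            for b in session.blocks
        ],
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    pd.DataFrame(
        {
            "onset_s": [e.onset for e in session.episodes],
            "offset_s": [e.offset for e in session.episodes],
            "partner_id": [e.partner_id for e in session.episodes],
            "partner_sex": [e.partner_sex for e in session.episodes],
        }
    ).to_csv(path / "episodes.csv", index=False)
    units_dir = path / "units"
    units_dir.mkdir(exist_ok=True)
    for uid, t in session.units.items():
        np.savetxt(units_dir / f"{uid}.csv", np.asarray(t), fmt="%.6f")
    return path


def read_session(path) -> Session:
    """Read a session bundle written by :func:`write_session`."""
    path = Path(path)
    if path.suffix == ".h5":
        return _read_h5(path)
    meta = json.loads((path / "session.json").read_text())
    blocks = [
        RecordingBlock(
            block_index=b["block_index"],
            start=b["start"],
            end=b["end"],
            partner_ids=frozenset(b.get("partner_ids", [])),
        )
        for b in meta["blocks"]
    ]
    df = pd.read_csv(path / "episodes.csv")
    missing = set(EPISODE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"episodes.csv missing columns {sorted(missing)}")
    episodes = [
        TouchEpisode(r.onset_s, r.offset_s, str(r.partner_id), str(r.partner_sex))
        for r in df.itertuples()
    ]
    units = {}
    units_dir = path / "units"
    if units_dir.is_dir():
        for f in sorted(units_dir.glob("*.csv")):
            units[f.stem] = np.atleast_1d(np.loadtxt(f, ndmin=1))
    return Session(
        subject_id=meta["subject_id"],
        subject_sex=meta["subject_sex"],
        area=meta["area"],
        blocks=blocks,
        episodes=episodes,
        units=units,
    )


def _write_h5(session: Session, path: Path) -> Path:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = session.subject_id
        f.attrs["subject_sex"] = session.subject_sex
        f.attrs["area"] = session.area
        g = f.create_group("blocks")
        g.create_dataset("block_index", data=[b.block_index for b in session.blocks])
        g.create_dataset("start", data=[b.start for b in session.blocks])
        g.create_dataset("end", data=[b.end for b in session.blocks])
        g.create_dataset(
            "partner_ids",
            data=[",".join(sorted(b.partner_ids)).encode() for b in session.blocks],
        )
        g = f.create_group("episodes")
        g.create_dataset("onset_s", data=[e.onset for e in session.episodes])
        g.create_dataset("offset_s", data=[e.offset for e in session.episodes])
        g.create_dataset(
            "partner_id", data=[e.partner_id.encode() for e in session.episodes]
        )
        g.create_dataset(
            "partner_sex", data=[e.partner_sex.encode() for e in session.episodes]
        )
        g = f.create_group("units")
        for uid, t in session.units.items():
            g.create_dataset(str(uid), data=np.asarray(t, dtype=float))
    return path


def _read_h5(path: Path) -> Session:
    import h5py

    with h5py.File(path, "r") as f:
        blocks = [
            RecordingBlock(
                block_index=int(i),
                start=float(s),
                end=float(e),
                partner_ids=frozenset(
                    p.decode().split(",") if p.decode() else []
                ),
            )
            for i, s, e, p in zip(
                f["blocks/block_index"][:],
                f["blocks/start"][:],
                f["blocks/end"][:],
                f["blocks/partner_ids"][:],
            )
        ]
        episodes = [
            TouchEpisode(float(a), float(b), p.decode(), s.decode())
            for a, b, p, s in zip(
                f["episodes/onset_s"][:],
                f["episodes/offset_s"][:],
                f["episodes/partner_id"][:],
                f["episodes/partner_sex"][:],
            )
        ]
        units = {uid: f["units"][uid][:] for uid in f["units"]}
        return Session(
            subject_id=str(f.attrs["subject_id"]),
            subject_sex=str(f.attrs["subject_sex"]),
            area=str(f.attrs["area"]),
            blocks=blocks,
            episodes=episodes,
            units=units,
        )
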