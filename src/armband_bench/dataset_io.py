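"""On-disk study layout for labeled armband recordings.

One cycle per file, mirroring the study's natural unit of train-set
ablation: ``root/p{participant}/{train,test}/{profile}/cycle{c}.emg16``
(packed little-endian 16-bit codes, channel-major frames — matching the
device's 2-byte transport) with a JSON sidecar carrying everything needed
to reconstruct volts and labels (rate, channel count, ENOB, full scale,
label runs, gesture boundary table, checksum).  A study-level
``manifest.json`` indexes the cycles and their checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .device_frontend import AcquiredRecording, DeviceProfile

__all__ = ["StudyError", "StudyLayout", "read_recording", "read_study",
           "write_recording", "write_study", "import_external_dataset"]

FORMAT_VERSION = "emg16/1"
SESSIONS = ("train", "test")


class StudyError(RuntimeError):
    """Structured persistence error; the message names the offending cycle."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _label_runs(labels: np.ndarray) -> list[list[int]]:
    runs: list[list[int]] = []
    for lab in labels:
        if runs and runs[-1][0] == int(lab):
            runs[-1][1] += 1
        else:
            runs.append([int(lab), 1])
    return runs


def _runs_to_labels(runs: list[list[int]]) -> np.ndarray:
    return np.concatenate([np.full(n, lab, dtype=np.int16) for lab, n in runs]) \
        if runs else np.empty(0, dtype=np.int16)


def write_recording(recording: AcquiredRecording, path: str | Path,
                    overwrite: bool = False) -> dict:
    """Persist one recording; returns its manifest entry.

    Codes are packed as little-endian uint16, channel-major frames (all
    channels of sample t, then sample t+1, ...).  The sidecar makes the
    write→read round trip bit-exact.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if (path.exists() or sidecar.exists()) and not overwrite:
        raise StudyError(f"{path} exists; pass overwrite=True to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)

    codes = np.asarray(recording.codes)
    if codes.ndim != 2:
        raise StudyError(f"{path}: codes must be (channels, time)")
    codes.T.astype("<u2").tofile(path)

    meta = {
        "format": FORMAT_VERSION,
        "profile": json.loads(recording.profile.to_json()),
        "rate": recording.rate,
        "n_channels": int(codes.shape[0]),
        "n_samples": int(codes.shape[1]),
        "label_runs": _label_runs(recording.labels),
        "boundaries": [[int(g), float(a), float(b)] for g, a, b in recording.boundaries],
        "sha256": _sha256(path),
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return {"data": path.name, "sidecar": sidecar.name,
            "sha256": meta["sha256"], "n_samples": meta["n_samples"],
            "n_channels": meta["n_channels"]}


def read_recording(path: str | Path, verify: bool = True) -> AcquiredRecording:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise StudyError(f"{path}: sidecar {sidecar.name} missing")
    meta = json.loads(sidecar.read_text())
    if meta.get("format") != FORMAT_VERSION:
        raise StudyError(f"{path}: unknown format {meta.get('format')!r}")
    n_ch, n_s = meta["n_channels"], meta["n_samples"]
    expected = n_ch * n_s * 2
    actual = path.stat().st_size
    if actual != expected:
        raise StudyError(f"{path}: truncated or padded data file "
                         f"({actual} bytes, expected {expected})")
    if verify and _sha256(path) != meta["sha256"]:
        raise StudyError(f"{path}: checksum mismatch (file corrupted or tampered)")
    codes = np.fromfile(path, dtype="<u2").reshape(n_s, n_ch).T
    labels = _runs_to_labels(meta["label_runs"])
    if labels.size != n_s:
        raise StudyError(f"{path}: label runs cover {labels.size} samples, data has {n_s}")
    prof = meta["profile"]
    prof["electrode_angles"] = tuple(prof.get("electrode_angles", ()))
    return AcquiredRecording(
        codes=np.ascontiguousarray(codes), rate=meta["rate"], labels=labels,
        profile=DeviceProfile(**prof),
        boundaries=[(int(g), float(a), float(b)) for g, a, b in meta["boundaries"]],
    )


# --------------------------------------------------------------------------
# study-level layout
# --------------------------------------------------------------------------

def _slice_cycles(rec: AcquiredRecording, cycles_per_session: int) -> list[AcquiredRecording]:
    n = rec.codes.shape[1]
    per = n // cycles_per_session
    out = []
    for c in range(cycles_per_session):
        a, b = c * per, (c + 1) * per
        t0, t1 = a / rec.rate, b / rec.rate
        bounds = [(g, s - t0, e - t0) for g, s, e in rec.boundaries
                  if s >= t0 - 1e-9 and e <= t1 + 1e-9]
        out.append(AcquiredRecording(
            codes=rec.codes[:, a:b], rate=rec.rate, labels=rec.labels[a:b],
            profile=rec.profile, boundaries=bounds))
    return out


def write_study(study, root: str | Path, overwrite: bool = False) -> Path:
    """Persist an in-memory synthetic study (see evaluation_stats) to disk."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    cycles_per_session = study.protocol.cycles_per_session
    entries: dict[str, dict] = {}
    for pid in study.participant_ids:
        for session in SESSIONS:
            for prof_name in study.profile_names:
                rec = study.recording(pid, session, prof_name)
                for c, cyc in enumerate(_slice_cycles(rec, cycles_per_session)):
                    rel = Path(f"p{pid:02d}") / session / prof_name / f"cycle{c}.emg16"
                    entry = write_recording(cyc, root / rel, overwrite=overwrite)
                    entries[str(rel)] = entry
    manifest = {
        "format": FORMAT_VERSION,
        "participants": [int(p) for p in study.participant_ids],
        "sessions": list(SESSIONS),
        "profiles": sorted(study.profile_names),
        "cycles_per_session": cycles_per_session,
        "seed": study.seed,
        "difficulty": study.difficulty,
        "cycles": entries,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return root


@dataclass
class StudyLayout:
    """Lazy view of a persisted study; cycles load (and verify) on access."""

    root: Path
    manifest: dict

    @property
    def participants(self) -> list[int]:
        return list(self.manifest["participants"])

    @property
    def profiles(self) -> list[str]:
        return list(self.manifest["profiles"])

    @property
    def cycles_per_session(self) -> int:
        return int(self.manifest["cycles_per_session"])

    @property
    def n_cycles(self) -> int:
        """Participant × session × cycle units (profile-independent)."""
        return len(self.participants) * len(self.manifest["sessions"]) * self.cycles_per_session

    def load_cycle(self, participant: int, session: str, cycle: int,
                   profile: str) -> AcquiredRecording:
        rel = Path(f"p{participant:02d}") / session / profile / f"cycle{cycle}.emg16"
        if str(rel) not in self.manifest["cycles"]:
            raise StudyError(f"cycle {rel} not listed in the manifest")
        return read_recording(self.root / rel)


def read_study(root: str | Path) -> StudyLayout:
    """Open a persisted study, validating manifest presence and completeness."""
    root = Path(root)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise StudyError(f"no manifest found under {root}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("format") != FORMAT_VERSION:
        raise StudyError(f"{mpath}: unknown study format {manifest.get('format')!r}")
    for rel in manifest["cycles"]:
        if not (root / rel).exists():
            raise StudyError(f"cycle {rel} missing from {root}")
    return StudyLayout(root=root, manifest=manifest)


def import_external_dataset(path: str | Path):  # pragma: no cover - stub
    """Adapter for the authors' published armband dataset (not implemented).

    The published repository's serialization is not described alongside the
    recordings this package simulates; an adapter must be written against
    that repository directly.  Nothing in this package depends on it.
    """
    raise NotImplementedError(
        "external dataset import is a stub; generate a synthetic study instead")
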