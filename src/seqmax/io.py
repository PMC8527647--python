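"""File formats and reproducibility plumbing.

Designed sequences go to FASTA (one record per run/sample, oracle score in
the header), optimized position probability matrices to MEME minimal motif
format, loss trajectories to JSON lines, and every run is accompanied by a
manifest that snapshots the configuration, seed and oracle spec needed to
reproduce it.  Structure-matching targets are exchanged as ``.npz`` archives
with named arrays (distance/theta/omega/phi) since no standard text format
exists for these tensors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .logits import Alphabet
from .objectives import DistributionTensors

PACKAGE_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(
    records: list[tuple[str, np.ndarray | str, float]],
    alphabet: Alphabet,
    path: str | Path,
) -> Path:
    """Write (name, sequence, score) triples as FASTA.

    Sequences may be one-hot matrices or strings; headers read
    ``>name score=<value to 6 decimals>``.
    """
    path = Path(path)
    seq_records = []
    for name, seq, score in records:
        if not isinstance(seq, str):
            seq = alphabet.decode(np.asarray(seq))
        seq_records.append(
            SeqRecord(Seq(seq), id=name, description=f"score={score:.6f}")
        )
    try:
        with path.open("w") as handle:
            SeqIO.write(seq_records, handle, "fasta")
    except OSError as exc:
        raise OSError(f"could not write FASTA to {path}: {exc}") from exc
    return path


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[tuple[str, np.ndarray]]:
    """Read a FASTA file back as (name, one-hot matrix) pairs."""
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        out.append((record.id, alphabet.encode(str(record.seq))))
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------


def _renormalize_row(row: np.ndarray) -> np.ndarray:
    """Round to 6 decimals and push the residual onto the largest entry."""
    rounded = np.round(row, 6)
    rounded[int(np.argmax(rounded))] += 1.0 - rounded.sum()
    return np.round(rounded, 6)


def write_pssm_meme(
    pssms: list[np.ndarray] | np.ndarray,
    alphabet: Alphabet,
    path: str | Path,
    names: list[str] | None = None,
) -> Path:
    """Write PSSMs in MEME minimal motif format (one motif per matrix)."""
    if isinstance(pssms, np.ndarray) and pssms.ndim == 2:
        pssms = [pssms]
    if names is None:
        names = [f"design_{i}" for i in range(len(pssms))]
    path = Path(path)
    m = alphabet.size
    bg = 1.0 / m
    lines = [
        "MEME version 4",
        "",
        f"ALPHABET= {alphabet.symbols}",
        "",
        "Background letter frequencies",
        " ".join(f"{s} {bg:.6f}" for s in alphabet.symbols),
        "",
    ]
    for name, pssm in zip(names, pssms):
        pssm = np.asarray(pssm, dtype=float)
        if pssm.ndim != 2 or pssm.shape[1] != m:
            raise ValueError(f"PSSM for {name!r} must be N x {m}")
        if pssm.min() < 0 or np.abs(pssm.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError(f"PSSM for {name!r} rows must be valid distributions")
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= {m} w= {pssm.shape[0]} "
            f"nsites= 1000000 E= 0"
        )
        for row in pssm:
            row = _renormalize_row(row)
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    path.write_text("\n".join(lines))
    return path


# ---------------------------------------------------------------------------
# JSONL trajectories
# ---------------------------------------------------------------------------

TRAJECTORY_KEYS = ("step", "train_loss", "test_loss", "gamma_summary")


def write_trajectory_jsonl(rows: list[dict], path: str | Path) -> Path:
    """Write per-update trajectory rows; schema {step, train_loss, test_loss,
    gamma_summary} with nulls where a field does not apply."""
    path = Path(path)
    with path.open("w") as handle:
        for row in rows:
            clean = {key: row.get(key) for key in TRAJECTORY_KEYS}
            handle.write(json.dumps(clean) + "\n")
    return path


def read_trajectory_jsonl(path: str | Path) -> list[dict]:
    """Read and schema-validate a trajectory file.

    Raises ``ValueError`` on missing keys or non-increasing step indices.
    """
    rows = []
    last_step = -1
    with Path(path).open() as handle:
        for line_no, line in enumerate(handle):
            row = json.loads(line)
            missing = [key for key in TRAJECTORY_KEYS if key not in row]
            if missing:
                raise ValueError(f"line {line_no}: missing keys {missing}")
            if row["step"] <= last_step:
                raise ValueError(
                    f"line {line_no}: step {row['step']} not strictly increasing"
                )
            last_step = row["step"]
            rows.append(row)
    return rows


def trajectory_rows_from_result(result) -> list[dict]:
    """Flatten a DesignResult into JSONL trajectory rows (run means)."""
    rows = []
    eval_lookup = {
        step: float(result.test_losses[:, i].mean())
        for i, step in enumerate(result.test_loss_steps)
    }
    for t in range(result.config.updates):
        rows.append(
            {
                "step": t,
                "train_loss": float(result.train_losses[:, t].mean()),
                "test_loss": eval_lookup.get(t),
                "gamma_summary": float(result.gamma_traj[:, t].mean())
                if result.gamma_traj is not None
                else None,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Structure-target archives
# ---------------------------------------------------------------------------


def save_structure_target(tensors: DistributionTensors, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(path, **tensors.as_dict())
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_structure_target(path: str | Path) -> DistributionTensors:
    with np.load(str(path)) as archive:
        return DistributionTensors(
            distance=archive["distance"],
            theta=archive["theta"],
            omega=archive["omega"],
            phi=archive["phi"],
        )


# ---------------------------------------------------------------------------
# YAML specs and run manifests
# ---------------------------------------------------------------------------


def load_yaml_spec(path: str | Path) -> dict:
    with Path(path).open() as handle:
        spec = yaml.safe_load(handle)
    if not isinstance(spec, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return spec


def dump_yaml_spec(spec: dict, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as handle:
        yaml.safe_dump(spec, handle, sort_keys=True)
    return path


@dataclass
class RunManifest:
    """Everything needed to reproduce a design run."""

    method: str
    seed: int
    config: dict
    oracle_spec: dict
    version: str = PACKAGE_VERSION
    outputs: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def config_snapshot(config) -> dict:
    """JSON-serializable snapshot of a DesignConfig."""
    snap = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if f.name == "alphabet":
            value = {"symbols": value.symbols, "mode": value.mode}
        elif f.name == "estimator":
            value = {"kind": value.kind, "temperature": value.temperature}
        snap[f.name] = value
    return snap
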