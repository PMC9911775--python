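"""File formats: hash-code tables, sample tables, YAML configs and optional
NIfTI single-slice ingestion.

All writes go through a write-temp-then-rename step so an interrupted run
never leaves a truncated table behind.  Indices are 0-based everywhere:
modalities are 0..M−1 in files and APIs.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ContractError, DataError, ParseError
from .model import ModelConfig
from .similarity import CodeMatrix, LabelSet
from .synthetic import PairedDataset, SyntheticConfig
from .training import TrainConfig


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Hash-code tables
# ---------------------------------------------------------------------------

@dataclass
class HashTable:
    """Flat table of binary codes: one row per (subject, modality)."""

    subject_ids: list
    modalities: np.ndarray
    class_index: np.ndarray
    bits: np.ndarray  # R×K in {−1, +1}

    def modality_list(self) -> list[int]:
        return sorted(set(int(m) for m in self.modalities))

    def for_modality(self, m: int):
        """(CodeMatrix, LabelSet-compatible class indices, ids) of one modality."""
        sel = np.flatnonzero(self.modalities == m)
        codes = CodeMatrix(self.bits[sel], modality_index=m, is_binary=True)
        cls = self.class_index[sel]
        ids = [self.subject_ids[i] for i in sel]
        return codes, cls, ids


def write_hash_table(codes, labels, ids, path, modality: int | None = None) -> None:
    """Serialize binary codes as TSV with header subject_id, modality, class,
    b1..bK.  ``codes`` is one CodeMatrix or a list of them (one per
    modality); strong pairing lets all share ``labels`` and ``ids``."""
    code_list = codes if isinstance(codes, (list, tuple)) else [codes]
    cls = labels.class_index if isinstance(labels, LabelSet) else np.asarray(labels, dtype=int)
    rows = []
    seen = set()
    k = code_list[0].n_bits
    for cm in code_list:
        if not cm.is_binary:
            raise ContractError("hash tables store binary codes; binarize first")
        if cm.n_bits != k:
            raise ParseError("all code matrices must share K")
        m = cm.modality_index if modality is None else modality
        for i in range(cm.n_samples):
            key = (ids[i], m)
            if key in seen:
                raise ContractError(f"duplicate (subject, modality) pair {key}")
            seen.add(key)
            bits = "\t".join(str(int(b)) for b in cm.values[i])
            rows.append(f"{ids[i]}\t{m}\t{int(cls[i])}\t{bits}")
    header = "subject_id\tmodality\tclass\t" + "\t".join(f"b{j + 1}" for j in range(k))
    atomic_write_text(path, "\n".join([header] + rows) + ("\n" if rows else "\n"))


def read_hash_table(path) -> HashTable:
    """Parse and validate a hash-code TSV; errors name the offending line."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file, missing header")
    header = lines[0].split("\t")
    if header[:3] != ["subject_id", "modality", "class"] or \
            any(h != f"b{j + 1}" for j, h in enumerate(header[3:])):
        raise ParseError(f"{path}: line 1: malformed header {lines[0]!r}")
    k = len(header) - 3
    if k < 1:
        raise ParseError(f"{path}: line 1: header declares no bit columns")
    ids, mods, cls, bits = [], [], [], []
    seen = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3 + k:
            raise ParseError(f"{path}: line {ln}: expected {3 + k} fields, got {len(parts)}")
        sid = parts[0]
        try:
            m, c = int(parts[1]), int(parts[2])
            row = [int(b) for b in parts[3:]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: non-integer field ({exc})") from None
        if any(b not in (-1, 1) for b in row):
            raise ParseError(f"{path}: line {ln}: bit values must be -1 or +1")
        if (sid, m) in seen:
            raise ParseError(f"{path}: line {ln}: duplicate (subject, modality) ({sid}, {m})")
        seen.add((sid, m))
        ids.append(sid)
        mods.append(m)
        cls.append(c)
        bits.append(row)
    return HashTable(
        subject_ids=ids,
        modalities=np.asarray(mods, dtype=int),
        class_index=np.asarray(cls, dtype=int),
        bits=np.asarray(bits, dtype=np.float64).reshape(len(ids), k),
    )


# ---------------------------------------------------------------------------
# Sample tables (the synthetic generator's on-disk format)
# ---------------------------------------------------------------------------

def write_dataset(dataset: PairedDataset, outdir) -> None:
    """One TSV per modality (subject_id, class, z1..zZ) plus labels.tsv."""
    outdir = Path(outdir)
    cls = dataset.labels.class_index
    z = dataset.input_dim
    header = "subject_id\tclass\t" + "\t".join(f"z{j + 1}" for j in range(z))
    for m in range(dataset.n_modalities):
        rows = [header]
        for i in range(dataset.n_subjects):
            vals = "\t".join(f"{v:.10g}" for v in dataset.samples[m, i])
            rows.append(f"{dataset.subject_ids[i]}\t{int(cls[i])}\t{vals}")
        atomic_write_text(outdir / f"modality{m}.tsv", "\n".join(rows) + "\n")
    lab_rows = ["subject_id\tclass"] + [
        f"{sid}\t{int(c)}" for sid, c in zip(dataset.subject_ids, cls)]
    atomic_write_text(outdir / "labels.tsv", "\n".join(lab_rows) + "\n")


def read_dataset(indir) -> PairedDataset:
    """Read back a directory written by :func:`write_dataset`."""
    indir = Path(indir)
    paths = sorted(indir.glob("modality*.tsv"),
                   key=lambda p: int(p.stem.removeprefix("modality")))
    if not paths:
        raise DataError(f"no modality*.tsv files under {indir}")
    per_mod, ids_ref, cls_ref = [], None, None
    for p in paths:
        lines = p.read_text().splitlines()
        ids, cls, vals = [], [], []
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            ids.append(parts[0])
            cls.append(int(parts[1]))
            vals.append([float(v) for v in parts[2:]])
        if ids_ref is None:
            ids_ref, cls_ref = ids, cls
        elif ids != ids_ref or cls != cls_ref:
            raise ParseError(f"{p}: subject order/labels disagree with {paths[0]} "
                             "(strong pairing violated)")
        per_mod.append(np.asarray(vals, dtype=np.float64))
    samples = np.stack(per_mod)
    n_classes = max(cls_ref) + 1
    return PairedDataset(samples=samples,
                         labels=LabelSet.from_class_index(cls_ref, n_classes),
                         subject_ids=ids_ref)


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

_SECTIONS = {"model": ModelConfig, "train": TrainConfig, "synthetic": SyntheticConfig}


def load_config(path) -> dict:
    """Parse a YAML/JSON config with optional sections model/train/synthetic,
    each validated against its dataclass schema."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    out = {}
    for section, payload in raw.items():
        if section not in _SECTIONS:
            raise ParseError(f"{path}: unknown section {section!r}; "
                             f"expected one of {sorted(_SECTIONS)}")
        cls = _SECTIONS[section]
        valid = set(cls.__dataclass_fields__)
        unknown = set(payload) - valid
        if unknown:
            raise ParseError(f"{path}: unknown keys in [{section}]: {sorted(unknown)}")
        out[section] = cls(**payload)
    return out


# ---------------------------------------------------------------------------
# NIfTI single-slice ingestion (optional real-data path)
# ---------------------------------------------------------------------------

def extract_slice(volume_path, axis: int = 2, index_policy="middle",
                  output_shape: tuple[int, int] | None = None):
    """Extract one 2-D slice from a NIfTI volume.

    ``index_policy`` is "middle" (0-based floor of (depth−1)/2) or an
    explicit integer index.  Intensities are min-max normalized to [0, 1]
    (a constant volume maps to zeros) and optionally resized by spline
    interpolation to ``output_shape``.  Returns (slice, metadata).
    """
    import nibabel as nib
    from scipy import ndimage

    volume_path = Path(volume_path)
    try:
        vol = np.asarray(nib.load(volume_path).get_fdata(), dtype=np.float64)
    except Exception as exc:
        raise OSError(f"cannot read NIfTI volume {volume_path}: {exc}") from exc
    if axis < 0 or axis >= vol.ndim:
        raise IndexError(f"axis {axis} out of range for a {vol.ndim}-D volume")
    depth = vol.shape[axis]
    if index_policy == "middle":
        index = (depth - 1) // 2
    else:
        index = int(index_policy)
        if not 0 <= index < depth:
            raise IndexError(f"slice index {index} out of range [0, {depth})")
    sl = np.take(vol, index, axis=axis)
    lo, hi = sl.min(), sl.max()
    sl = (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)
    if output_shape is not None:
        factors = (output_shape[0] / sl.shape[0], output_shape[1] / sl.shape[1])
        sl = ndimage.zoom(sl, factors, order=1)
        sl = np.clip(sl, 0.0, 1.0)
    meta = {"source": str(volume_path), "axis": axis, "index": index,
            "original_shape": tuple(int(s) for s in vol.shape)}
    return sl, meta
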