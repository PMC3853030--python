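"""Reading and writing barcode manifests, metadata sidecars and manifests.

Barcode sets travel as plain TSV (columns ``id``, ``sequence``) or FASTA,
accompanied by a JSON sidecar (``<file>.json``) recording the code's
metric, dmin, n and filter policy so that decoding never has to guess the
code's guarantees.  Both formats round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import BarcodeSet, verify_code
from .filters import FilterPolicy
from .sequences import SequenceError, validate


class ManifestFormatError(ValueError):
    """Malformed barcode manifest (duplicate ids, bad characters, ragged rows)."""


_FASTA_SUFFIXES = {".fa", ".fasta", ".fna"}


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_barcode_set(
    code: BarcodeSet,
    path: str | Path,
    policy: FilterPolicy | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a barcode set as TSV or FASTA (by extension) plus JSON sidecar."""
    path = Path(path)
    ids = code.sample_ids()
    if path.suffix.lower() in _FASTA_SUFFIXES:
        records = [
            SeqRecord(Seq(seq), id=sid, description="") for sid, seq in zip(ids, code.barcodes)
        ]
        SeqIO.write(records, path, "fasta")
    else:
        with open(path, "w") as fh:
            fh.write("id\tsequence\n")
            for sid, seq in zip(ids, code.barcodes):
                fh.write(f"{sid}\t{seq}\n")
    meta = {
        "n": code.n,
        "metric": code.metric,
        "dmin": code.dmin,
        "k": code.k,
        "guaranteed_correction_dna": code.guaranteed_correction_dna,
        "size": len(code),
    }
    if policy is not None:
        meta["filter_policy"] = dataclasses.asdict(policy)
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_barcode_manifest(
    path: str | Path,
    metric: str | None = None,
    dmin: int | None = None,
    verify: bool = True,
) -> BarcodeSet:
    """Load a barcode set from TSV or FASTA, normalising case.

    ``metric``/``dmin`` override or replace sidecar metadata; one of the
    two sources must provide them.  Lowercase sequences are uppercased;
    non-ACGT characters, duplicate ids and ragged lengths raise
    :class:`ManifestFormatError` naming the offending record.  With
    ``verify=True`` the pairwise distance invariant is checked before the
    set is returned.
    """
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    if path.suffix.lower() in _FASTA_SUFFIXES:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            ids.append(rec.id)
            try:
                seqs.append(validate(str(rec.seq), name=f"record {i} ({rec.id})"))
            except SequenceError as exc:
                raise ManifestFormatError(str(exc)) from None
    else:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or (i == 1 and line.lower().startswith("id\t")):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ManifestFormatError(f"line {i}: expected 2 tab-separated columns")
                sid, seq = parts
                ids.append(sid)
                try:
                    seqs.append(validate(seq, name=f"line {i} ({sid})"))
                except SequenceError as exc:
                    raise ManifestFormatError(str(exc)) from None
    if not seqs:
        raise ManifestFormatError(f"{path}: no barcodes found")
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ManifestFormatError(f"duplicate ids: {', '.join(dupes)}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ManifestFormatError(f"ragged barcode lengths: {sorted(lengths)}")

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    metric = metric or meta.get("metric")
    dmin = dmin if dmin is not None else meta.get("dmin")
    if metric is None or dmin is None:
        raise ManifestFormatError(
            f"{path}: metric/dmin not given and no sidecar {sc.name} found"
        )
    code = BarcodeSet(n=lengths.pop(), metric=metric, dmin=int(dmin), barcodes=seqs, ids=ids)
    if verify:
        ok, violations = verify_code(code)
        if not ok:
            raise ManifestFormatError(
                f"{path}: {len(violations)} pairwise distance violation(s), "
                f"first: {violations[0]}"
            )
    return code


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(
    out_path: str | Path,
    command: str,
    parameters: dict,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> Path:
    """Record one CLI invocation: command, parameters, seeds, file digests."""
    from . import __version__

    manifest = {
        "command": command,
        "parameters": parameters,
        "package_version": __version__,
        "python": sys.version.split()[0],
        "input_digests": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
        "output_digests": {str(p): file_digest(p) for p in outputs if Path(p).exists()},
    }
    out_path = Path(out_path)
    out_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return out_path
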