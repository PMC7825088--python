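"""Readers and writers for every on-disk format used by the pipeline.

FASTA via Biopython, MGF via pyteomics, tables and labeled matrices as TSV
(Cytoscape-importable edge lists). All writers order rows lexicographically
by id so outputs are byte-identical across runs. Fingerprints are
serialized as hex strings with the declared bit length in a header comment
line.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .families import CompoundRecord
from .similarity import BGCRecord
from .specnet import Spectrum


class FormatError(ValueError):
    """A file is syntactically malformed."""


class SchemaError(ValueError):
    """A table is missing required columns or violates its contract."""


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str          # upper-cased
    has_ambiguous: bool    # contains non-ACGT characters (preserved)


_ACGT = frozenset("ACGT")


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA; sequences are upper-cased, non-ACGT content is flagged."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file (line 1)")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        lineno = next(i for i, l in enumerate(text.splitlines(), 1)
                      if l.strip())
        raise FormatError(
            f"{path}: line {lineno}: expected '>' header, got {first[:30]!r}")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: record with empty header id")
        records.append(FastaRecord(
            id=rec.id, sequence=seq,
            has_ambiguous=not _ACGT.issuperset(seq)))
    return records


def write_fasta(records: list[FastaRecord] | dict[str, str],
                path: str | Path) -> None:
    """Write FASTA, rows ordered lexicographically by id."""
    if isinstance(records, dict):
        records = [FastaRecord(i, s.upper(), not _ACGT.issuperset(s.upper()))
                   for i, s in records.items()]
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="")
            for r in sorted(records, key=lambda r: r.id)]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


_BGC_COLUMNS = ("bgc_id", "genome_id", "class", "complete_flag",
                "domains", "domain_seqs")


def read_bgc_table(path: str | Path) -> list[BGCRecord]:
    """Read the BGC TSV (semicolon-joined domain architecture columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _BGC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[list(_BGC_COLUMNS)]  # fix positions: "class" -> itertuples _2
    records = []
    for row in df.itertuples(index=False):
        records.append(BGCRecord(
            id=row.bgc_id,
            genome_id=row.genome_id,
            class_label=getattr(row, "_2"),  # "class" is a keyword
            complete_flag=str(row.complete_flag).lower()
            in ("true", "1", "yes"),
            domains=tuple(row.domains.split(";")),
            domain_seqs=tuple(row.domain_seqs.split(";")),
        ))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise SchemaError(f"{path}: duplicate bgc_id values")
    return records


def write_bgc_table(records: list[BGCRecord], path: str | Path) -> None:
    df = pd.DataFrame({
        "bgc_id": [r.id for r in records],
        "genome_id": [r.genome_id for r in records],
        "class": [r.class_label for r in records],
        "complete_flag": [r.complete_flag for r in records],
        "domains": [";".join(r.domains) for r in records],
        "domain_seqs": [";".join(r.domain_seqs) for r in records],
    }).sort_values("bgc_id", kind="stable")
    df.to_csv(path, sep="\t", index=False)


def _fp_to_hex(fp: np.ndarray) -> str:
    return np.packbits(fp.astype(np.uint8)).tobytes().hex()


def _hex_to_fp(hexstr: str, n_bits: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
    return np.unpackbits(raw)[:n_bits].astype(bool)


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read paired BGC<->compound records with hex-encoded fingerprints.

    The declared bit length comes from a ``# fingerprint_bits=N`` header
    comment line.
    """
    path = Path(path)
    n_bits = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "fingerprint_bits=" in line:
                    n_bits = int(line.split("fingerprint_bits=")[1].strip())
            else:
                break
    if n_bits is None:
        raise SchemaError(f"{path}: missing '# fingerprint_bits=N' header")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ("compound_id", "bgc_id", "fingerprint")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return [CompoundRecord(compound_id=row.compound_id, bgc_id=row.bgc_id,
                           fingerprint=_hex_to_fp(row.fingerprint, n_bits))
            for row in df.itertuples(index=False)]


def write_compound_table(records: list[CompoundRecord],
                         path: str | Path) -> None:
    if not records:
        raise ValueError("no compound records to write")
    n_bits = int(records[0].fingerprint.size)
    for r in records:
        if r.fingerprint.size != n_bits:
            raise ValueError("fingerprint lengths differ across records")
    df = pd.DataFrame({
        "compound_id": [r.compound_id for r in records],
        "bgc_id": [r.bgc_id for r in records],
        "fingerprint": [_fp_to_hex(r.fingerprint) for r in records],
    }).sort_values("compound_id", kind="stable")
    with open(path, "w") as fh:
        fh.write(f"# fingerprint_bits={n_bits}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read spectra from MGF; entries with empty peak lists are rejected."""
    spectra = []
    with _mgf.read(str(path), use_index=False) as reader:
        for entry in reader:
            params = entry["params"]
            sid = str(params.get("title", f"scan_{len(spectra)}"))
            mz = np.asarray(entry["m/z array"], dtype=float)
            if mz.size == 0:
                raise FormatError(f"{path}: spectrum {sid!r} has an empty "
                                  "peak list")
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise FormatError(f"{path}: spectrum {sid!r} missing PEPMASS")
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list))
                              else pepmass)
            charge = int(params.get("charge", [1])[0])
            spectra.append(Spectrum(
                id=sid, precursor_mz=precursor, charge=charge,
                mz=mz, intensity=np.asarray(entry["intensity array"],
                                            dtype=float)))
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    entries = [{
        "m/z array": s.mz,
        "intensity array": s.intensity,
        "params": {"title": s.id, "pepmass": s.precursor_mz,
                   "charge": s.charge},
    } for s in sorted(spectra, key=lambda s: s.id)]
    _mgf.write(entries, str(path), file_mode="w")


def write_edge_list(edges: list[tuple], path: str | Path,
                    columns: tuple[str, ...] = ("source", "target", "score"),
                    ) -> None:
    """Cytoscape-importable TSV edge list, sorted by (source, target)."""
    df = pd.DataFrame(edges, columns=list(columns)[:len(edges[0])]
                      if edges else list(columns))
    if edges:
        df = df.sort_values(list(df.columns[:2]), kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_matrix(labels: list[str], values: np.ndarray,
                 path: str | Path) -> None:
    """Labeled square matrix as TSV, rows/columns in lexicographic order."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(np.asarray(labels, dtype=object))
    labels_sorted = [labels[i] for i in order]
    v = values[np.ix_(order, order)]
    pd.DataFrame(v, index=labels_sorted, columns=labels_sorted).to_csv(
        path, sep="\t", float_format="%.12g")


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a labeled square matrix; validates squareness and symmetry."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if list(map(str, df.columns)) != labels:
        raise SchemaError(f"{path}: row and column labels differ "
                          "(matrix not square-labeled)")
    v = df.to_numpy(dtype=float)
    if v.shape[0] != v.shape[1]:
        raise SchemaError(f"{path}: matrix not square: {v.shape}")
    if not np.allclose(v, v.T, atol=1e-9):
        raise SchemaError(f"{path}: matrix not symmetric within 1e-9")
    return labels, v
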