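"""Readers and writers for every on-disk format the pipeline touches.

All genomic records are 0-based half-open in memory; BED-family inputs are
already 0-based, refGene-style tables likewise (UCSC txStart/txEnd).
Bespoke tables are tab-separated with '#'-prefixed header lines; every
writer stamps the config hash when one is provided.  ``read(write(x))``
round-trips exactly for each format.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hmm_core import HmmModel
from .obs_encoding import GeneRecord, MarkPeak, NucleosomeRecord, ObservationSequence
from .splicing import SeEvent


class FormatError(ValueError):
    """Malformed input line, with file/line context."""


def _fail(path, lineno: int, msg: str):
    raise FormatError(f"{path}:{lineno}: {msg}")


def _header_lines(config_hash: str | None, extra: dict | None = None) -> list[str]:
    lines = []
    if config_hash:
        lines.append(f"#cfg={config_hash}")
    if extra:
        lines.append("#meta=" + json.dumps(extra, sort_keys=True))
    return lines


def _read_meta(path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("#meta="):
                meta = json.loads(line[len("#meta=") :])
    return meta


# ---------------------------------------------------------------------------
# nucleosome attribute table (caller output dialect)

INPS_COLUMNS = (
    "chrom",
    "start",
    "end",
    "dyad",
    "height",
    "width",
    "area",
    "pval_peak",
    "pval_valley",
    "signal",
)


def _fmt(value) -> str:
    """Round-tripping float formatting (repr of a Python float)."""
    return repr(float(value))


def write_inps(path, nucleosomes: Sequence[NucleosomeRecord], config_hash=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config_hash):
            fh.write(line + "\n")
        fh.write("#" + "\t".join(INPS_COLUMNS) + "\n")
        for nuc in nucleosomes:
            signal = ",".join(_fmt(v) for v in nuc.signal) or "."
            fields = (
                nuc.chrom, nuc.start, nuc.end, nuc.dyad, _fmt(nuc.height),
                _fmt(nuc.width), _fmt(nuc.area), _fmt(nuc.pval_peak),
                _fmt(nuc.pval_valley), signal,
            )
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_inps(path, column_map: dict[str, int] | None = None) -> list[NucleosomeRecord]:
    """Read a per-nucleosome attribute table.

    ``column_map`` overrides the default column positions (name -> 0-based
    index) to accommodate other caller dialects; ``dyad`` and ``signal``
    may be omitted from the map (dyad defaults to the midpoint).
    """
    cmap = {name: i for i, name in enumerate(INPS_COLUMNS)}
    if column_map:
        cmap.update(column_map)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                chrom = parts[cmap["chrom"]]
                start = int(parts[cmap["start"]])
                end = int(parts[cmap["end"]])
                dyad = (
                    int(parts[cmap["dyad"]])
                    if "dyad" in cmap and cmap["dyad"] < len(parts)
                    else (start + end) // 2
                )
                sig_idx = cmap.get("signal")
                raw_sig = (
                    parts[sig_idx] if sig_idx is not None and sig_idx < len(parts) else "."
                )
                signal = (
                    tuple(float(v) for v in raw_sig.split(",")) if raw_sig != "." else ()
                )
                records.append(
                    NucleosomeRecord(
                        chrom=chrom,
                        start=start,
                        end=end,
                        dyad=dyad,
                        height=float(parts[cmap["height"]]),
                        width=float(parts[cmap["width"]]),
                        area=float(parts[cmap["area"]]),
                        pval_peak=float(parts[cmap["pval_peak"]]),
                        pval_valley=float(parts[cmap["pval_valley"]]),
                        signal=signal,
                    )
                )
            except (IndexError, ValueError) as exc:
                _fail(path, lineno, f"bad nucleosome record ({exc})")
    return records


# ---------------------------------------------------------------------------
# BED family

def read_bed_intervals(path, min_fields: int = 3) -> list[tuple]:
    """Generic BED3+ reader -> list of (chrom, start, end, *rest) tuples."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < min_fields:
                _fail(path, lineno, f"expected >= {min_fields} fields, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
            except ValueError as exc:
                _fail(path, lineno, f"bad coordinates ({exc})")
    return rows


def write_bed_intervals(path, rows: Sequence[tuple], config_hash=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config_hash):
            fh.write(line + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_narrowpeak(path) -> list[tuple[str, int, int]]:
    """narrowPeak (BED6+4) -> (chrom, start, end); checks the column count."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(("#", "track")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 10:
                _fail(path, lineno, f"narrowPeak requires 10 columns, got {len(parts)}")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_broadpeak(path) -> list[tuple[str, int, int]]:
    """broadPeak (BED6+3) -> (chrom, start, end)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(("#", "track")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                _fail(path, lineno, f"broadPeak requires 9 columns, got {len(parts)}")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_peaks_as_marks(paths_by_mark: dict[int, str]) -> list[MarkPeak]:
    """Load one peak file per mark bit; format chosen by extension.

    ``.narrowPeak`` -> narrowPeak, ``.broadPeak`` -> broadPeak, anything
    else is read as generic BED3+.
    """
    peaks: list[MarkPeak] = []
    for mark_id, path in paths_by_mark.items():
        name = str(path)
        if name.endswith(".narrowPeak"):
            rows = read_narrowpeak(path)
        elif name.endswith(".broadPeak"):
            rows = read_broadpeak(path)
        else:
            rows = [(c, s, e) for c, s, e, *_ in read_bed_intervals(path)]
        peaks.extend(MarkPeak(c, s, e, mark_id) for c, s, e in rows)
    return peaks


def write_mark_peaks(path, peaks: Sequence[MarkPeak], mark_id: int, fmt: str = "narrowPeak") -> None:
    """Write one mark's peaks in narrowPeak or broadPeak layout."""
    rows = [p for p in peaks if p.mark_id == mark_id]
    with open(path, "w") as fh:
        for i, p in enumerate(rows):
            base = f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t0\t.\t0\t-1\t-1"
            if fmt == "narrowPeak":
                fh.write(base + "\t-1\n")
            elif fmt == "broadPeak":
                fh.write(base + "\n")
            else:
                raise ValueError(f"unknown peak format {fmt!r}")


# ---------------------------------------------------------------------------
# gene annotation

def read_refgene(path) -> list[GeneRecord]:
    """refGene-style table: name, chrom, strand, txStart, txEnd (0-based).

    Accepts the UCSC dump layout (leading bin column) or a headerless
    5-column table.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 6 and parts[0].isdigit():
                parts = parts[1:]  # UCSC leading bin column
            if len(parts) < 5:
                _fail(path, lineno, "need name, chrom, strand, txStart, txEnd")
            name, chrom, strand = parts[0], parts[1], parts[2]
            try:
                tx_start, tx_end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                _fail(path, lineno, f"bad coordinates ({exc})")
            if strand == "+":
                genes.append(GeneRecord(chrom, tx_start, tx_end, "+", name))
            else:
                genes.append(GeneRecord(chrom, tx_end, tx_start, "-", name))
    return genes


def write_refgene(path, genes: Sequence[GeneRecord], config_hash=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config_hash):
            fh.write(line + "\n")
        for g in genes:
            left, right = min(g.tss, g.tts), max(g.tss, g.tts)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{left}\t{right}\n")


def read_bed12_genes(path) -> list[GeneRecord]:
    genes = []
    for row in read_bed_intervals(path, min_fields=12):
        chrom, start, end, name = row[0], row[1], row[2], row[3]
        strand = row[5]
        if strand == "+":
            genes.append(GeneRecord(chrom, start, end, "+", name))
        else:
            genes.append(GeneRecord(chrom, end, start, "-", name))
    return genes


def unique_tss(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Deduplicate genes sharing a 5'TSS; ties break by gene_id order."""
    chosen: dict[tuple[str, str, int], GeneRecord] = {}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        key = (gene.chrom, gene.strand, gene.tss)
        chosen.setdefault(key, gene)
    return sorted(chosen.values(), key=lambda g: (g.chrom, min(g.tss, g.tts), g.gene_id))


# ---------------------------------------------------------------------------
# observation sequences

def write_obs_sequences(
    path,
    sequences: Sequence[ObservationSequence],
    nucleosomes: Sequence[NucleosomeRecord],
    mark_order: Sequence[str],
    config_hash=None,
) -> None:
    """TSV of (gene_id, chrom, dyad, symbol) with a JSON metadata header."""
    meta = {"mark_order": list(mark_order)}
    with open(path, "w") as fh:
        for line in _header_lines(config_hash, meta):
            fh.write(line + "\n")
        fh.write("#gene_id\tchrom\tdyad\tsymbol\n")
        for seq in sequences:
            for ref, symbol in zip(seq.nucleosome_refs, seq.symbols):
                nuc = nucleosomes[ref]
                fh.write(f"{seq.gene_id}\t{nuc.chrom}\t{nuc.dyad}\t{symbol}\n")


def read_obs_sequences(path) -> tuple[list[ObservationSequence], tuple[str, ...]]:
    """Inverse of :func:`write_obs_sequences`.

    ``nucleosome_refs`` become (chrom, dyad) pairs.  Rows for one gene must
    be contiguous (as written).
    """
    meta = _read_meta(path)
    mark_order = tuple(meta.get("mark_order", ()))
    sequences = []
    current: str | None = None
    symbols: list[int] = []
    refs: list[tuple[str, int]] = []

    def flush() -> None:
        if current is not None:
            sequences.append(ObservationSequence(current, tuple(symbols), tuple(refs)))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                _fail(path, lineno, f"expected 4 fields, got {len(parts)}")
            gene_id, chrom, dyad, symbol = parts
            if gene_id != current:
                flush()
                current, symbols, refs = gene_id, [], []
            try:
                symbols.append(int(symbol))
                refs.append((chrom, int(dyad)))
            except ValueError as exc:
                _fail(path, lineno, f"bad record ({exc})")
    flush()
    return sequences, mark_order


# ---------------------------------------------------------------------------
# model JSON

def write_model(
    path,
    model: HmmModel,
    mark_order: Sequence[str] = (),
    seed: int | None = None,
    trace: Sequence[float] = (),
    config_hash=None,
) -> None:
    doc = {
        "pi": model.pi.tolist(),
        "A": model.A.tolist(),
        "B": model.B.tolist(),
        "mark_order": list(mark_order),
        "seed": seed,
        "log_likelihood_trace": list(trace),
        "config_hash": config_hash,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_model(path) -> tuple[HmmModel, dict]:
    with open(path) as fh:
        doc = json.load(fh)
    model = HmmModel(np.array(doc["pi"]), np.array(doc["A"]), np.array(doc["B"]))
    meta = {k: doc.get(k) for k in ("mark_order", "seed", "log_likelihood_trace", "config_hash")}
    return model, meta


def write_matrix_tsv(path, matrix: np.ndarray, row_labels, col_labels) -> None:
    pd.DataFrame(matrix, index=row_labels, columns=col_labels).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# decoded states

def write_state_bed(
    path,
    nucleosomes: Sequence[NucleosomeRecord],
    states: Sequence[int],
    config_hash=None,
) -> None:
    """BED6 with the state as the name field (score 0, strand '.')."""
    rows = [
        (n.chrom, n.start, n.end, f"S{int(s)}", 0, ".")
        for n, s in zip(nucleosomes, states)
    ]
    write_bed_intervals(path, rows, config_hash)


def read_state_bed(path) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    rows = read_bed_intervals(path, min_fields=4)
    coords = [(c, s, e) for c, s, e, *_ in rows]
    states = np.array([int(row[3].lstrip("S")) for row in rows], dtype=np.int64)
    return coords, states


# ---------------------------------------------------------------------------
# tables

def write_table(path, frame: pd.DataFrame, config_hash=None) -> None:
    """Bespoke TSV: '#'-prefixed header lines, then the dataframe."""
    with open(path, "w") as fh:
        for line in _header_lines(config_hash):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_se_events(path, events: Sequence[SeEvent], config_hash=None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config_hash):
            fh.write(line + "\n")
        fh.write("#event_id\tchrom\tstart\tend\tstrand\tx_reads\ty_reads\tci_width\n")
        for e in events:
            fh.write(
                f"{e.event_id}\t{e.chrom}\t{e.start}\t{e.end}\t{e.strand}\t"
                f"{e.x_reads}\t{e.y_reads}\t{_fmt(e.ci_width)}\n"
            )


def read_se_events(path) -> list[SeEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 8:
                _fail(path, lineno, f"expected 8 fields, got {len(parts)}")
            try:
                events.append(
                    SeEvent(
                        event_id=parts[0],
                        chrom=parts[1],
                        start=int(parts[2]),
                        end=int(parts[3]),
                        strand=parts[4],
                        x_reads=int(parts[5]),
                        y_reads=int(parts[6]),
                        ci_width=float(parts[7]),
                    )
                )
            except ValueError as exc:
                _fail(path, lineno, f"bad SE event ({exc})")
    return events
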