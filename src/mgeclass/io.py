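"""FASTA input and tabular result output.

The FASTA reader is deliberately small so it can report malformed
records with line numbers (sequence data before any header, records
with empty sequences); it accepts multi-line records, Windows line
endings, and lower-case sequence (upper-cased on read). Record ids are
the first whitespace-delimited token of the header; a ``label=X`` token
in the header is picked up as the true class when present.
"""

from __future__ import annotations

from pathlib import Path

from .fragments import CLASSES, DnaFragment
from .windows import Prediction

RESULT_COLUMNS = ("id", "length", "phage_score", "chromosome_score",
                  "plasmid_score", "label")


def read_fasta(path: str | Path) -> list[DnaFragment]:
    fragments: list[DnaFragment] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(
                f"{path}: record {header!r} (line {header_line}) has an "
                f"empty sequence")
        tokens = header.split()
        label = None
        for tok in tokens[1:]:
            if tok.startswith("label="):
                value = tok[len("label="):]
                if value in CLASSES:
                    label = value
        fragments.append(DnaFragment(id=tokens[0], seq=seq, label=label))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise ValueError(f"{path}: empty header at line {lineno}")
            else:
                if header is None:
                    raise ValueError(
                        f"{path}: sequence data before any header at line "
                        f"{lineno}")
                chunks.append(line.strip().upper())
        flush()
    return fragments


def write_results(predictions: list[Prediction], path: str | Path) -> None:
    """Header plus one tab-separated row per prediction, scores to 4 dp."""
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for pred in predictions:
            s = pred.scores
            fh.write(f"{pred.id}\t{pred.length}\t{s.phage:.4f}\t"
                     f"{s.chromosome:.4f}\t{s.plasmid:.4f}\t{pred.label}\n")


def read_results(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if tuple(header) != RESULT_COLUMNS:
            raise ValueError(f"{path}: unexpected result columns {header}")
        for line in fh:
            parts = line.rstrip("\r\n").split("\t")
            rows.append({
                "id": parts[0], "length": int(parts[1]),
                "phage_score": float(parts[2]),
                "chromosome_score": float(parts[3]),
                "plasmid_score": float(parts[4]), "label": parts[5],
            })
    return rows


def read_truth_table(path: str | Path) -> dict[str, str]:
    """id -> true label from the simulator's sidecar table."""
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        id_col = header.index("id")
        label_col = header.index("label")
        for line in fh:
            parts = line.rstrip("\r\n").split("\t")
            out[parts[id_col]] = parts[label_col]
    return out
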