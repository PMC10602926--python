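"""Readers and writers for the pipeline's file formats.

Formats handled: UTR FASTA (record ids ``<transcript>|5utr`` /
``<transcript>|3utr``, or plain ids with the UTR kind given per file),
RIP enrichment TSV, LRE site tables (TSV and BED6), gene lists (one id
per line, ``#`` comments), dot-bracket structure files, the YAML scoring
model config and per-run JSON manifests.

Coordinates are 0-based half-open in the site TSV and BED output.  Every
reader/writer pair round-trips its in-memory representation; parsers
report the file and record/line of the offending token.  DNA-alphabet
input (T, lowercase) is normalised to uppercase RNA on load.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from .binding import BindingScore, RipRecord
from .errors import InputError
from .model import ScoringModel
from .pipeline import GeneSet
from .scan import LreSite, RnaSequence, TranscriptLreProfile

logger = logging.getLogger("lretools")

_UTR_SUFFIX = {"5utr": "five_prime", "3utr": "three_prime"}
_UTR_SUFFIX_INV = {v: k for k, v in _UTR_SUFFIX.items()}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_utr_fasta(
    path: str | Path, utr_kind: Optional[str] = None
) -> List[RnaSequence]:
    """Read UTR sequences from FASTA.

    With ``utr_kind`` given, record ids are plain transcript ids of that
    kind (a matching ``|5utr``/``|3utr`` suffix is tolerated and
    stripped; a contradicting one is an error); otherwise ids must
    follow the ``<transcript>|5utr`` / ``<transcript>|3utr`` convention.
    Lowercase and T are normalised; duplicate (transcript, kind) ids are
    an error naming the id.
    """
    path = Path(path)
    out: List[RnaSequence] = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        rid = record.id
        if utr_kind is not None:
            tid, kind = rid, utr_kind
            if "|" in rid:
                stem, suffix = rid.rsplit("|", 1)
                if suffix in _UTR_SUFFIX:
                    if _UTR_SUFFIX[suffix] != utr_kind:
                        raise InputError(
                            f"{path}: record {rid!r} is tagged {suffix!r} but "
                            f"the file was declared {utr_kind}"
                        )
                    tid = stem
        else:
            if "|" not in rid:
                raise InputError(
                    f"{path}: record {rid!r} lacks the '|5utr'/'|3utr' suffix"
                )
            tid, suffix = rid.rsplit("|", 1)
            if suffix not in _UTR_SUFFIX:
                raise InputError(
                    f"{path}: record {rid!r} has unknown UTR suffix {suffix!r}"
                )
            kind = _UTR_SUFFIX[suffix]
        key = (tid, kind)
        if key in seen:
            raise InputError(f"{path}: duplicate record id {rid!r}")
        seen.add(key)
        raw = str(record.seq)
        if raw != raw.upper().replace("T", "U"):
            logger.info("%s: record %s normalised to uppercase RNA", path, rid)
        try:
            out.append(RnaSequence.from_raw(tid, kind, raw))
        except InputError as exc:
            raise InputError(f"{path}: {exc}") from exc
    return out


def write_utr_fasta(seqs: Sequence[RnaSequence], path: str | Path,
                    width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            fh.write(f">{s.id}|{_UTR_SUFFIX_INV[s.utr_kind]}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def pair_utrs(
    seqs: Sequence[RnaSequence],
) -> Dict[str, Dict[str, RnaSequence]]:
    """Group UTR records by transcript id: {tid: {utr_kind: RnaSequence}}."""
    out: Dict[str, Dict[str, RnaSequence]] = {}
    for s in seqs:
        slot = out.setdefault(s.id, {})
        if s.utr_kind in slot:
            raise InputError(f"duplicate {s.utr_kind} UTR for transcript {s.id!r}")
        slot[s.utr_kind] = s
    return out


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path, name: Optional[str] = None) -> GeneSet:
    """One identifier per line; '#' starts a comment; CRLF tolerated."""
    path = Path(path)
    members = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        if any(ch.isspace() for ch in body):
            raise InputError(
                f"{path}:{lineno}: expected a single identifier, got {body!r}"
            )
        members.append(body)
    return GeneSet.from_iterable(name or path.stem, members)


def write_gene_list(geneset: GeneSet, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in sorted(geneset.members))
    )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_rip_table(path: str | Path) -> List[RipRecord]:
    """RIP TSV with header columns transcript_id, log2_enrichment."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "log2_enrichment"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    dup = df["transcript_id"].duplicated()
    if dup.any():
        raise InputError(
            f"{path}: duplicate transcript ids "
            f"{sorted(df.loc[dup, 'transcript_id'].unique())[:5]}"
        )
    try:
        return [
            RipRecord(str(t), float(e))
            for t, e in zip(df["transcript_id"], df["log2_enrichment"])
        ]
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}: non-numeric enrichment value ({exc})") from exc


def write_rip_table(rip: Sequence[RipRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in rip],
            "log2_enrichment": [r.log2_enrichment for r in rip],
        }
    ).to_csv(path, sep="\t", index=False)


SITE_COLUMNS = (
    "seq_id", "utr_kind", "start", "end", "stem_len", "loop", "score", "category",
)


def profiles_to_site_frame(
    profiles: Sequence[TranscriptLreProfile],
) -> pd.DataFrame:
    """Flatten profiles into the site table (0-based half-open coordinates)."""
    rows = []
    for p in profiles:
        for kind, site in p.all_sites():
            start, end = site.span
            rows.append(
                {
                    "seq_id": p.transcript_id,
                    "utr_kind": kind,
                    "start": start,
                    "end": end,
                    "stem_len": site.hairpin.stem_len,
                    "loop": site.hairpin.loop,
                    "score": site.score,
                    "category": site.category,
                }
            )
    return pd.DataFrame(rows, columns=list(SITE_COLUMNS))


def write_site_table(
    profiles: Sequence[TranscriptLreProfile], path: str | Path
) -> None:
    profiles_to_site_frame(profiles).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    return df


def write_scores_table(scores: Sequence[BindingScore], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in scores],
            "binding_score": [s.value for s in scores],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed(profiles: Sequence[TranscriptLreProfile], path: str | Path) -> None:
    """BED6: chrom = '<transcript>|<utr suffix>', 0-based half-open,
    name = category, score = model score x 1000 rounded, strand '+'."""
    with Path(path).open("w") as fh:
        for p in profiles:
            for kind, site in p.all_sites():
                start, end = site.span
                chrom = f"{p.transcript_id}|{_UTR_SUFFIX_INV[kind]}"
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{site.category}\t"
                    f"{round(site.score * 1000)}\t+\n"
                )


def read_bed(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\r").split("\t")
        if len(fields) < 6:
            raise InputError(f"{path}:{lineno}: expected 6 BED fields")
        try:
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                    "name": fields[3],
                    "score": int(fields[4]),
                    "strand": fields[5],
                }
            )
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


# ---------------------------------------------------------------------------
# Dot-bracket structure files
# ---------------------------------------------------------------------------


def read_structure_file(path: str | Path) -> Dict[str, str]:
    """Structures for the folding import path.

    Format: per record a '>' id line followed by one dot-bracket line,
    matching the FASTA ids of the sequences they describe.
    """
    path = Path(path)
    out: Dict[str, str] = {}
    current: Optional[str] = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\r").strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            if current in out:
                raise InputError(f"{path}:{lineno}: duplicate structure id {current!r}")
            out[current] = ""
        else:
            if current is None:
                raise InputError(f"{path}:{lineno}: structure line before any '>' id")
            out[current] += line
    return out


# ---------------------------------------------------------------------------
# Config and manifests
# ---------------------------------------------------------------------------


def load_model_config(path: str | Path) -> ScoringModel:
    """Load a :class:`ScoringModel` from a YAML key-value file."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return ScoringModel()
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a mapping")
    return ScoringModel.from_dict(data)


def save_model_config(model: ScoringModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=True))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    inputs: Iterable[str | Path] = (),
    seed: Optional[int] = None,
    config: Optional[dict] = None,
    deterministic: bool = False,
) -> None:
    """Per-run JSON manifest: seed, config hash and input checksums.

    With ``deterministic`` the wall-clock timestamp is suppressed so two
    identical runs produce byte-identical manifests.
    """
    manifest: dict = {
        "command": command,
        "seed": seed,
        "inputs": {
            str(p): file_sha256(p) for p in inputs if Path(p).exists()
        },
    }
    if config is not None:
        blob = json.dumps(config, sort_keys=True).encode()
        manifest["config_sha256"] = hashlib.sha256(blob).hexdigest()
        manifest["config"] = config
    if not deterministic:
        import datetime

        manifest["timestamp"] = datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
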