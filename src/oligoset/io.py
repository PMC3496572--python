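"""File formats, run configuration and the published-set library.

Sequence I/O is FASTA (via Biopython) or plain text (one sequence per
line, blank lines ignored, identifiers auto-numbered). All sequences are
normalized on ingest: lowercase is uppercased, anything outside ACGT is
rejected with the offending record and position named.

Outputs of a generation run are written as a FASTA of the set (5'->3',
uppercase), an optional audit report as TSV + JSON, and a JSON metadata
sidecar carrying the constraints, the seed, the package version and the
completeness flag — enough to regenerate the set exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .analysis import AuditReport
from .constraints import DesignConstraints
from .generator import SequenceSet
from .sequences import AlphabetError, normalize

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_outputs",
    "RunConfig",
    "PublishedSet",
    "load_published_sets",
]


def read_sequences(path: str | Path, format: str = "auto") -> list[tuple[str, str]]:
    """Ordered ``(identifier, sequence)`` pairs from a FASTA or plain file.

    ``format`` is ``fasta``, ``plain``, or ``auto`` (FASTA iff the first
    non-blank character is ``>``). Plain files hold one sequence per line;
    identifiers are auto-numbered from 1.
    """
    path = Path(path)
    text = path.read_text()
    if format == "auto":
        stripped = text.lstrip()
        format = "fasta" if stripped.startswith(">") else "plain"
    out: list[tuple[str, str]] = []
    if format == "fasta":
        for rec in SeqIO.parse(path, "fasta"):
            try:
                out.append((rec.id, normalize(str(rec.seq), name=f"record {rec.id!r}")))
            except AlphabetError as e:
                raise AlphabetError(f"{path}: {e}") from None
    elif format == "plain":
        n = 0
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            n += 1
            try:
                out.append((str(n), normalize(line, name=f"line {lineno}")))
            except AlphabetError as e:
                raise AlphabetError(f"{path}: {e}") from None
    else:
        raise ValueError(f"unknown format {format!r} (use fasta, plain or auto)")
    return out


def write_fasta(
    sequences: SequenceSet | list[str] | list[tuple[str, str]], path: str | Path
) -> Path:
    """Write sequences as FASTA (uppercase, 5'->3'); returns the path."""
    path = Path(path)
    records = []
    if isinstance(sequences, SequenceSet):
        items = [(str(i + 1), s) for i, s in enumerate(sequences.sequences)]
    elif sequences and isinstance(sequences[0], tuple):
        items = list(sequences)
    else:
        items = [(str(i + 1), s) for i, s in enumerate(sequences)]
    for sid, s in items:
        records.append(SeqRecord(Seq(s), id=str(sid), description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")
    return path


def _constraints_to_dict(c: DesignConstraints) -> dict:
    d = dataclasses.asdict(c)
    d["forbidden_motifs"] = list(d["forbidden_motifs"])
    d["included_sequences"] = list(d["included_sequences"])
    return d


def constraints_from_dict(d: dict) -> DesignConstraints:
    return DesignConstraints(**d)


def write_outputs(
    result: SequenceSet,
    out_prefix: str | Path,
    report: AuditReport | None = None,
) -> dict[str, Path]:
    """Write ``<prefix>.fasta``, ``<prefix>.meta.json`` and, when an audit
    report is given, ``<prefix>.audit.tsv`` + ``<prefix>.audit.json``.

    The metadata sidecar contains the constraints and the seed, so the run
    can be regenerated exactly.
    """
    from . import __version__

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": write_fasta(result, prefix.with_suffix(".fasta"))}
    meta = {
        "version": __version__,
        "seed": result.seed,
        "complete": result.complete,
        "n_sequences": len(result),
        "runtime_seconds": result.runtime,
        "constraints": _constraints_to_dict(result.constraints),
    }
    meta_path = prefix.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    paths["meta"] = meta_path
    if report is not None:
        tsv = prefix.with_suffix(".audit.tsv")
        report.per_sequence_frame().to_csv(tsv, sep="\t", index=False)
        paths["audit_tsv"] = tsv
        audit_json = prefix.with_suffix(".audit.json")
        audit_json.write_text(
            json.dumps(
                {
                    "clean": report.clean,
                    "max_interstrand_word": report.max_interstrand_word,
                    "max_internal_repeat": report.max_internal_repeat,
                    "max_palindrome": report.max_palindrome,
                    "max_hairpin_stem": report.max_hairpin_stem,
                    "violations": [list(v) for v in report.violations],
                },
                indent=1,
            )
            + "\n"
        )
        paths["audit_json"] = audit_json
    return paths


@dataclass(frozen=True)
class RunConfig:
    """A full run description, loadable from YAML and overridable by CLI flags."""

    constraints: DesignConstraints
    out_prefix: str = "oligoset_run"
    n_runs: int = 1
    log_level: str = "WARNING"

    def to_dict(self) -> dict:
        return {
            "constraints": _constraints_to_dict(self.constraints),
            "out_prefix": self.out_prefix,
            "n_runs": self.n_runs,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            constraints=constraints_from_dict(d["constraints"]),
            out_prefix=d.get("out_prefix", "oligoset_run"),
            n_runs=d.get("n_runs", 1),
            log_level=d.get("log_level", "WARNING"),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# published reference/comparison sets shipped with the package


@dataclass(frozen=True)
class PublishedSet:
    """A published oligonucleotide set with its design parameters.

    ``origin`` is ``"reference"`` for sets published with the original
    implementation of this design algorithm and ``"comparison"`` for sets
    from prior design tools, shipped for benchmarking the auditor.
    """

    name: str
    description: str
    origin: str
    sequences: tuple[str, ...]
    params: dict

    def constraints(self) -> DesignConstraints:
        """Audit constraints implied by the set's published parameters."""
        p = self.params
        return DesignConstraints(
            seq_length=max(len(s) for s in self.sequences),
            criton_length=p["criton_length"],
            lhp=p["lhp"],
            lsc=p["lsc"],
            lsl=p["lsl"],
            gc_ends=p["gc_ends"],
        )


def load_published_sets() -> dict[str, PublishedSet]:
    """All published sets shipped with the package, keyed by name."""
    base = resources.files("oligoset").joinpath("data/published")
    meta = json.loads(base.joinpath("sets.json").read_text())
    out = {}
    for name, info in meta.items():
        seqs = tuple(
            normalize(line.strip())
            for line in base.joinpath(info["file"]).read_text().splitlines()
            if line.strip() and not line.startswith(">")
        )
        out[name] = PublishedSet(
            name=name,
            description=info["description"],
            origin=info["origin"],
            sequences=seqs,
            params=info["params"],
        )
    return out
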