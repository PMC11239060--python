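"""One-shot report runs: orchestrate all stages from a single config.

A run config (YAML, or a :class:`RunConfig` built in code) names the input
alignment and group table and lists which markers, polymorphism tables,
difference counts and spore summaries to produce.  ``run_report`` writes a
deterministic bundle of TSV/JSON/plain-text artifacts plus a log that
echoes the full configuration, so any bundle can be regenerated from its
log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .alignment import read_alignment
from .diffs import group_unique_sites, species_vs_sample_differences
from .errors import InputError, ItsdiagError
from .markers import discover_and_format
from .morphometry import SporeMeasurementSet, render_summary, summarize_spores
from .sites import polymorphic_positions, render_table, heteromorphism_flags

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    alignment: str  # path to aligned FASTA
    groups: str | None = None  # path to sample<TAB>group TSV
    out_dir: str = "itsdiag_report"
    marker_groups: list[dict] = dataclasses.field(default_factory=list)
    # each: {group, coords: local|alignment, ref: sample|None, window: int}
    tables: list[list[str]] = dataclasses.field(default_factory=list)  # sample subsets
    diff_pairs: list[dict] = dataclasses.field(default_factory=list)
    # each: {a, b, sample: optional, exclude_heteromorphic: bool, indel_mode}
    spores: str | None = None  # path to measurement TSV
    seed: int = 0

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict) or "alignment" not in data:
            raise InputError("run config must be a mapping with an 'alignment' key")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


def run_report(config: RunConfig) -> list[Path]:
    """Execute every configured stage; returns the paths written.

    On any stage failure the files written so far in this run are removed
    and the error re-raised with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        written.append(path)

    stage = "load"
    try:
        alignment_text = Path(config.alignment).read_text()
        groups_text = Path(config.groups).read_text() if config.groups else None
        matrix = read_alignment(alignment_text, groups_text)

        stage = "markers"
        marker_lines: list[str] = []
        marker_rows: list[str] = ["marker\tcolumns\tmode\tgroup"]
        for spec in config.marker_groups:
            group = spec["group"]
            markers = discover_and_format(
                matrix,
                group,
                coordinate_mode=spec.get("coords", "local"),
                reference_sample=spec.get("ref"),
                window_width=int(spec.get("window", 13)),
            )
            for m in markers:
                marker_lines.append(f"{group}: {m.notation()}")
                cols = ",".join(str(c) for c in m.columns)
                marker_rows.append(f"{m.notation()}\t{cols}\t{m.coordinate_mode}\t{group}")
        if config.marker_groups:
            emit("markers.txt", "\n".join(marker_lines) + "\n")
            emit("markers.tsv", "\n".join(marker_rows) + "\n")

        stage = "polymorphism-tables"
        for idx, subset in enumerate(config.tables, start=1):
            table = polymorphic_positions(matrix, subset)
            emit(f"polymorphic_positions_{idx}.tsv", render_table(table))
            emit(
                f"polymorphic_positions_{idx}.flags.json",
                json.dumps(
                    {s: {str(c): v for c, v in row.items()}
                     for s, row in heteromorphism_flags(table).items()},
                    indent=2,
                    sort_keys=True,
                ),
            )

        stage = "difference-counts"
        diff_reports = []
        for spec in config.diff_pairs:
            kwargs = dict(
                exclude_heteromorphic=bool(spec.get("exclude_heteromorphic", True)),
                indel_mode=spec.get("indel_mode", "column"),
            )
            if "sample" in spec:
                rep = species_vs_sample_differences(matrix, spec["a"], spec["sample"], **kwargs)
                label = f"{spec['a']} vs sample {spec['sample']}"
            else:
                rep = group_unique_sites(matrix, spec["a"], spec["b"], **kwargs)
                label = f"{spec['a']} vs {spec['b']}"
            diff_reports.append({"comparison": label, **kwargs, **rep.to_dict()})
        if config.diff_pairs:
            emit("differences.json", json.dumps(diff_reports, indent=2))
            rows = ["comparison\tdifferences\tcounted\texcluded_het\texcluded_missing\tpositions"]
            for r in diff_reports:
                rows.append(
                    f"{r['comparison']}\t{r['differences']}\t{r['counted_columns']}\t"
                    f"{r['excluded_heteromorphic']}\t{r['excluded_missing']}\t"
                    + ",".join(str(p) for p in r["difference_positions"])
                )
            emit("differences.tsv", "\n".join(rows) + "\n")

        stage = "morphometry"
        if config.spores:
            ms = SporeMeasurementSet.from_tsv(Path(config.spores).read_text())
            summary = summarize_spores(ms)
            emit("spores.txt", render_summary(summary) + "\n")
            emit(
                "spores.json",
                json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True),
            )

        stage = "log"
        emit(
            "run.log",
            f"itsdiag {__version__}\nseed: {config.seed}\n--- config ---\n" + config.to_yaml(),
        )
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        logger.error("stage %r failed; partial outputs removed", stage)
        raise ItsdiagError(f"stage {stage!r} failed: {exc}") from exc
    return written
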