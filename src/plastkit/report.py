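"""Cross-species comparison reports and the staged analysis pipeline.

``compare_genomes`` lines up per-species genome summaries side by side
(genome and region lengths, GC%, gene counts, ...) and flags the per-row
minimum and maximum, reproducing the shape of the printed six-palm
comparison.  ``run_pipeline`` executes the analysis stages in dependency
order on one genome and writes their TSV/JSON outputs plus a parameter log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .codons import count_codons, extract_cds_codons, rscu, usage_records
from .errors import ConfigError, SchemaError, StageDependencyError
from .model import gc_content, read_annotation, read_genome
from .quadripartite import (
    detect_inverted_repeat_pair,
    junction_profile,
    partition_quadripartite,
)
from .repeats import annotate_repeats, find_exact_repeats

log = logging.getLogger(__name__)


@dataclass
class ComparisonReport:
    """Side-by-side species table with per-row min/max annotations."""

    table: pd.DataFrame  # characteristics x species
    minima: dict[str, str]  # characteristic -> species holding the minimum
    maxima: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["min"] = [self.minima.get(idx, "") for idx in out.index]
        out["max"] = [self.maxima.get(idx, "") for idx in out.index]
        return out


def compare_genomes(inputs: list[dict]) -> ComparisonReport:
    """Tabulate per-species result dicts and flag per-row extremes.

    Each input dict must contain ``species`` plus an identical set of
    numeric fields.  Ties are not flagged (neither minimum nor maximum is
    reported when two species share the extreme value).
    """
    if len(inputs) < 2:
        raise SchemaError("need at least two species to compare")
    keys = set(inputs[0]) - {"species"}
    for row in inputs[1:]:
        if set(row) - {"species"} != keys:
            raise SchemaError(
                f"inconsistent field sets: {sorted(keys)} vs {sorted(set(row) - {'species'})}"
            )
    species = [row["species"] for row in inputs]
    characteristics = sorted(keys)
    table = pd.DataFrame(
        {row["species"]: [row[c] for c in characteristics] for row in inputs},
        index=characteristics,
    )
    minima, maxima = {}, {}
    for c in characteristics:
        values = table.loc[c]
        if values.min() != values.max():
            if (values == values.min()).sum() == 1:
                minima[c] = values.idxmin()
            if (values == values.max()).sum() == 1:
                maxima[c] = values.idxmax()
    return ComparisonReport(table=table, minima=minima, maxima=maxima)


KNOWN_STAGES = ("partition", "junctions", "codon_usage", "repeats")


def run_pipeline(config: dict) -> dict:
    """Run the requested stages on one genome and write their outputs.

    ``config`` keys: ``genome`` (FASTA path), ``annotation`` (TSV path,
    required for junctions/codon_usage), ``stages`` (list), ``outdir``,
    and optional stage parameters (``min_ir``, ``min_period``,
    ``max_period``, ``min_copies``, ``junction_genes``).  Stages run in
    dependency order; requesting ``junctions`` without ``partition``
    raises :class:`StageDependencyError`.  Reruns with the same config are
    byte-identical.
    """
    for key in ("genome", "stages", "outdir"):
        if key not in config:
            raise ConfigError(f"config missing required key {key!r}")
    unknown = set(config["stages"]) - set(KNOWN_STAGES)
    if unknown:
        raise ConfigError(
            f"unknown stages {sorted(unknown)}; known: {list(KNOWN_STAGES)}"
        )
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in KNOWN_STAGES if s in config["stages"]]
    log.info("plastkit %s pipeline: stages %s", __version__, stages)

    seq = read_genome(config["genome"])
    annotations = None
    if config.get("annotation"):
        annotations = read_annotation(config["annotation"], genome_length=len(seq))

    outputs: dict[str, Path] = {}
    partition = None
    for stage in stages:
        if stage == "partition":
            ir_pair = detect_inverted_repeat_pair(
                seq, min_length=config.get("min_ir", 1000)
            )
            partition = partition_quadripartite(seq, ir_pair)
            payload = partition.to_dict()
            payload["gc_content"] = round(gc_content(seq), 6)
            path = outdir / "partition.json"
            path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
            outputs[stage] = path
        elif stage == "junctions":
            if partition is None:
                raise StageDependencyError(
                    "junctions requires the partition stage output"
                )
            if annotations is None:
                raise ConfigError("junctions requires an annotation table")
            genes = config.get(
                "junction_genes", sorted({a.gene_name for a in annotations})
            )
            profiles = junction_profile(
                partition, annotations, genes, species=seq.identifier
            )
            path = outdir / "junctions.tsv"
            with open(path, "w") as fh:
                fh.write("species\tgene\tjunction\tdistance\n")
                for p in profiles:
                    fh.write(f"{p.species}\t{p.gene}\t{p.junction}\t{p.distance}\n")
            outputs[stage] = path
        elif stage == "codon_usage":
            if annotations is None:
                raise ConfigError("codon_usage requires an annotation table")
            table = rscu(count_codons(extract_cds_codons(seq, annotations)))
            path = outdir / "codon_usage.tsv"
            with open(path, "w") as fh:
                fh.write("codon\taa\tcount\trscu\n")
                for row in usage_records(table):
                    value = "" if row["rscu"] is None else f"{row['rscu']:.2f}"
                    fh.write(f"{row['codon']}\t{row['aa']}\t{row['count']}\t{value}\n")
            outputs[stage] = path
        elif stage == "repeats":
            records = find_exact_repeats(
                seq,
                min_period=config.get("min_period", 11),
                max_period=config.get("max_period", 500),
                min_copies=config.get("min_copies", 2),
            )
            if annotations is not None:
                records = annotate_repeats(records, annotations, partition)
            path = outdir / "repeats.tsv"
            with open(path, "w") as fh:
                fh.write("size\tpositions\tcopies\ttype\tsequence\tregion\n")
                for rec in records:
                    row = rec.to_row()
                    fh.write(
                        "\t".join(
                            str(row[k])
                            for k in (
                                "size",
                                "positions",
                                "copies",
                                "type",
                                "sequence",
                                "region",
                            )
                        )
                        + "\n"
                    )
            outputs[stage] = path
    manifest = {
        "version": __version__,
        "config": {k: str(v) for k, v in config.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (outdir / "run.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {"outputs": outputs, "manifest": manifest}
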