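"""Packaged fixtures: verbatim transcriptions of the printed reference tables.

Four tables and one figure from the coconut plastome study ship with the
package as plain TSV / newick transcriptions: the codon-usage table
(counts and printed RSCU), the 13-row repeat table, the six-palm genome
comparison, the RNA-editing site table with RT-PCR outcomes, and the
monocot phylogeny with its gene gain/duplication/pseudogenization/loss
character states.  Transcriptions preserve printed values verbatim —
including internally inconsistent rows, which are flagged by validators
but never silently corrected.  Each file carries a sha256 checksum,
verified at load time.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .editing import EditingSite
from .errors import FixtureIntegrityError, SchemaError
from .parsimony import CharacterMatrix, PhyloTree, read_newick
from .repeats import RepeatRecord

FIXTURE_FILES = {
    "table2": "table2.tsv",
    "table3": "table3.tsv",
    "table5": "table5.tsv",
    "table6": "table6.tsv",
    "fig3_tree": "fig3_tree.nwk",
    "fig3_chars": "fig3_chars.tsv",
}


def _read_data(filename: str) -> str:
    ref = resources.files("plastkit").joinpath("data", filename)
    return ref.read_text()


def _verify(table_id: str, text: str) -> None:
    registry = json.loads(_read_data("checksums.json"))
    digest = hashlib.sha256(text.encode()).hexdigest()
    expected = registry[FIXTURE_FILES[table_id]]
    if digest != expected:
        raise FixtureIntegrityError(
            f"fixture {table_id}: checksum {digest[:12]}... != expected {expected[:12]}..."
        )


def load_fixture(table_id: str):
    """Load a packaged fixture as typed records.

    ``table2`` -> DataFrame (aa, codon as printed, codon_dna, count,
    rscu_printed, trna); ``table3`` -> list of RepeatRecord (positions
    0-based); ``table5`` -> DataFrame indexed by characteristic;
    ``table6`` -> list of EditingSite; ``fig3_tree`` -> PhyloTree;
    ``fig3_chars`` -> CharacterMatrix.
    """
    if table_id not in FIXTURE_FILES:
        raise SchemaError(
            f"unknown fixture {table_id!r}; available: {sorted(FIXTURE_FILES)}"
        )
    text = _read_data(FIXTURE_FILES[table_id])
    _verify(table_id, text)
    loader = {
        "table2": _load_table2,
        "table3": _load_table3,
        "table5": _load_table5,
        "table6": _load_table6,
        "fig3_tree": _load_tree,
        "fig3_chars": _load_chars,
    }[table_id]
    return loader(text)


def _load_table2(text: str) -> pd.DataFrame:
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", dtype={"count": int})
    df["trna"] = df.get("trna", pd.Series(dtype=str)).fillna("")
    df["codon_dna"] = df["codon"].str.replace("U", "T")
    if len(df) != 61:
        raise SchemaError(f"codon table has {len(df)} rows, expected 61 sense codons")
    if df["codon_dna"].isin(["TAA", "TAG", "TGA"]).any():
        raise SchemaError("codon table contains stop codons")
    if df["codon_dna"].duplicated().any():
        raise SchemaError("duplicate codons in table")
    return df


def _load_table3(text: str) -> list[RepeatRecord]:
    records = []
    lines = text.strip().split("\n")
    for line in lines[1:]:
        fields = line.split("\t")
        no, size, positions, copies, rtype, sequence, region = fields[:7]
        note = fields[7] if len(fields) > 7 else ""
        positions_0 = tuple(int(p) - 1 for p in positions.split(","))
        if len(sequence) != int(size):
            raise SchemaError(f"repeat {no}: unit length != printed size")
        if len(positions_0) != int(copies):
            raise SchemaError(f"repeat {no}: position count != printed copy number")
        records.append(
            RepeatRecord(
                unit=sequence,
                period=int(size),
                copies=int(copies),
                positions=positions_0,
                repeat_type=rtype,
                region_note=region,
                is_rc_partner=note.startswith("inverted_of"),
            )
        )
    if len(records) != 13:
        raise SchemaError(f"repeat table has {len(records)} rows, expected 13")
    return records


def _load_table5(text: str) -> pd.DataFrame:
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", index_col="characteristic")
    if list(df.columns) != [
        "Calamus",
        "Pseudophoenix",
        "Phoenix",
        "Bismarckia",
        "Elaeis",
        "Cocos",
    ]:
        raise SchemaError("unexpected species columns in comparison table")
    if int(df.loc["size_bp", "Cocos"]) != 154_731:
        raise SchemaError("Cocos genome size does not match the printed 154,731 bp")
    return df


def _load_table6(text: str) -> list[EditingSite]:
    sites = []
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        before, after = row["codon_change"].split("-")
        aa_from, aa_to = row["aa_change"].split("-")
        sites.append(
            EditingSite(
                gene=row["gene"],
                cds_position=int(row["nt_position"]),
                codon_change=(before, after),
                codon_position=int(row["codon_position"]),
                aa_change=(aa_from, aa_to),
                predicted=row["predicted"] == "1",
                rtpcr=row["rtpcr"],
                shared_with_oil_palm=row["shared"] == "1",
            )
        )
    return sites


def _load_tree(text: str) -> PhyloTree:
    tree = read_newick(text.strip())
    if tree.n_leaves != 25:
        raise SchemaError(f"phylogeny fixture has {tree.n_leaves} leaves, expected 25")
    return tree


def _load_chars(text: str) -> CharacterMatrix:
    lines = text.strip().split("\n")
    characters = lines[0].split("\t")[1:]
    states: dict[tuple[str, str], str] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        for char, state in zip(characters, fields[1:]):
            states[(fields[0], char)] = state
    return CharacterMatrix(characters=characters, states=states)
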