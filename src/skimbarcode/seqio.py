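"""Alignment and metadata I/O, and supermatrix assembly.

The analysis operates on per-region multiple sequence alignments (one FASTA
per genetic region) plus a sample metadata table (TSV: sample_id, taxon,
population).  Regions are concatenated into coded data sets (A-G by default):

    A  plastid protein-coding genes
    B  mitochondrial protein-coding genes
    C  plastid intergenic spacers
    D  complete nrDNA cistron (18S-ITS1-5.8S-ITS2-26S)
    E  internal transcribed spacer (ITS1-5.8S-ITS2)
    F  core barcode matK + rbcL
    G  divergence hotspot regions

Column coordinates are 0-based half-open everywhere in code; report tables
render 1-based inclusive spans for human readers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import encode_matrix
from .errors import AlignmentError, FormatError, MissingSampleError

COMPARTMENTS = ("plastid_gene", "plastid_spacer", "mito_gene", "nrDNA_part")
ORGANELLAR_COMPARTMENTS = ("plastid_gene", "plastid_spacer", "mito_gene")
DATASET_CODES = ("A", "B", "C", "D", "E", "F", "G")

NRDNA_PARTS = ("18S", "ITS1", "5.8S", "ITS2", "26S")
ITS_PARTS = ("ITS1", "5.8S", "ITS2")

#: Default data-set membership.  Sets defined by compartment pull in every
#: region of that compartment (in region order); sets defined by name use
#: exactly the listed regions in the listed order.
DEFAULT_DATASET_DEFINITIONS: dict[str, dict] = {
    "A": {"compartment": "plastid_gene"},
    "B": {"compartment": "mito_gene"},
    "C": {"compartment": "plastid_spacer"},
    "D": {"regions": list(NRDNA_PARTS)},
    "E": {"regions": list(ITS_PARTS)},
    "F": {"regions": ["matK", "rbcL"]},
    "G": {"regions": ["rps1", "rps2", "rps14", "ycf3-psaA", "trnE-clpP"]},
}


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    taxon: str
    population: str


@dataclass
class RegionAlignment:
    """One aligned genetic region over a common sample set.

    ``sequences[i]`` belongs to ``samples[i]``; all sequences have equal
    length and are stored uppercase (U mapped to T on read).
    """

    region_name: str
    compartment: str
    samples: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.sequences):
            raise AlignmentError(
                f"{self.region_name}: {len(self.samples)} sample ids for "
                f"{len(self.sequences)} sequences"
            )
        if len(set(self.samples)) != len(self.samples):
            raise FormatError(f"{self.region_name}: duplicate sample ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(
                f"{self.region_name}: unequal sequence lengths {sorted(lengths)}"
            )
        self.sequences = [s.upper().replace("U", "T") for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def encoded(self) -> np.ndarray:
        return encode_matrix(self.sequences)

    def sequence_of(self, sample_id: str) -> str:
        return self.sequences[self.samples.index(sample_id)]

    def subset(self, sample_ids: list[str]) -> "RegionAlignment":
        """Restrict to the given samples, preserving the requested order."""
        missing = [s for s in sample_ids if s not in self.samples]
        if missing:
            raise MissingSampleError(
                f"{self.region_name}: samples absent from alignment: {missing}"
            )
        return RegionAlignment(
            region_name=self.region_name,
            compartment=self.compartment,
            samples=list(sample_ids),
            sequences=[self.sequence_of(s) for s in sample_ids],
        )


@dataclass
class ConcatenatedDataSet:
    """A supermatrix for one data-set code with its partition map.

    ``partition_map`` maps region name -> (start, stop) column span,
    0-based half-open; spans are disjoint, contiguous and cover the full
    alignment length.
    """

    code: str
    alignment: RegionAlignment
    partition_map: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.partition_map.values())
        pos = 0
        for start, stop in spans:
            if start != pos or stop <= start:
                raise AlignmentError(
                    f"data set {self.code}: partition map spans are not "
                    f"contiguous/disjoint: {spans}"
                )
            pos = stop
        if pos != self.alignment.length:
            raise AlignmentError(
                f"data set {self.code}: partition map covers {pos} of "
                f"{self.alignment.length} columns"
            )

    @property
    def length(self) -> int:
        return self.alignment.length

    def region_slice(self, region_name: str) -> "RegionAlignment":
        """Recover one constituent region by slicing the supermatrix."""
        start, stop = self.partition_map[region_name]
        return RegionAlignment(
            region_name=region_name,
            compartment=self.alignment.compartment,
            samples=list(self.alignment.samples),
            sequences=[s[start:stop] for s in self.alignment.sequences],
        )


def read_fasta_alignment(
    path: str | Path, region_name: str | None = None, compartment: str = ""
) -> RegionAlignment:
    """Read an aligned FASTA file into a :class:`RegionAlignment`.

    Sequences are uppercased; ragged lengths, duplicate headers and empty
    files are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    samples = [r.id for r in records]
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate FASTA headers")
    sequences = [str(r.seq) for r in records]
    if len({len(s) for s in sequences}) > 1:
        raise AlignmentError(f"{path}: sequences have unequal lengths")
    return RegionAlignment(
        region_name=region_name or path.stem,
        compartment=compartment,
        samples=samples,
        sequences=sequences,
    )


def write_fasta_alignment(alignment: RegionAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.samples, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (columns sample_id, taxon, population)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "taxon", "population"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: metadata must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id values")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def concatenate_regions(
    regions: list[RegionAlignment], code: str, pad_missing: bool = False
) -> ConcatenatedDataSet:
    """Concatenate region alignments column-wise into one supermatrix.

    All regions must share an identical sample set (order may differ); the
    output sample order is taken from the first region.  With
    ``pad_missing`` a sample absent from some region gets an all-N row over
    that region's span instead of raising.
    """
    if not regions:
        raise AlignmentError(f"data set {code}: no regions to concatenate")
    names = [r.region_name for r in regions]
    if len(set(names)) != len(names):
        raise AlignmentError(f"data set {code}: duplicate region names {names}")
    sample_order = list(regions[0].samples)
    universe = set(sample_order)
    for r in regions[1:]:
        extra = set(r.samples) - universe
        if extra:
            sample_order.extend(s for s in r.samples if s in extra)
            universe |= extra
    if not pad_missing:
        for r in regions:
            missing = universe - set(r.samples)
            if missing:
                raise MissingSampleError(
                    f"data set {code}: region {r.region_name} lacks samples "
                    f"{sorted(missing)} (use pad_missing to fill with N)"
                )
    parts: dict[str, list[str]] = {s: [] for s in sample_order}
    partition_map: dict[str, tuple[int, int]] = {}
    pos = 0
    for r in regions:
        row = dict(zip(r.samples, r.sequences))
        for s in sample_order:
            parts[s].append(row.get(s, "N" * r.length))
        partition_map[r.region_name] = (pos, pos + r.length)
        pos += r.length
    alignment = RegionAlignment(
        region_name=f"dataset_{code}",
        compartment=regions[0].compartment
        if len({r.compartment for r in regions}) == 1
        else "",
        samples=sample_order,
        sequences=["".join(parts[s]) for s in sample_order],
    )
    return ConcatenatedDataSet(code=code, alignment=alignment, partition_map=partition_map)


def extract_its(
    nrdna_parts: list[RegionAlignment], code: str = "E"
) -> ConcatenatedDataSet:
    """Build the ITS data set (ITS1-5.8S-ITS2, in that order)."""
    by_name = {r.region_name: r for r in nrdna_parts}
    missing = [p for p in ITS_PARTS if p not in by_name]
    if missing:
        raise MissingSampleError(f"nrDNA parts missing for ITS set: {missing}")
    return concatenate_regions([by_name[p] for p in ITS_PARTS], code)


def build_datasets(
    regions: list[RegionAlignment],
    definitions: dict[str, dict] | None = None,
    pad_missing: bool = False,
) -> dict[str, ConcatenatedDataSet]:
    """Assemble all coded data sets from the region pool.

    ``definitions`` follows :data:`DEFAULT_DATASET_DEFINITIONS`: per code
    either ``{"compartment": name}`` or ``{"regions": [names...]}``.
    """
    definitions = definitions or DEFAULT_DATASET_DEFINITIONS
    by_name = {r.region_name: r for r in regions}
    datasets: dict[str, ConcatenatedDataSet] = {}
    for code, spec in definitions.items():
        if "compartment" in spec:
            members = [r for r in regions if r.compartment == spec["compartment"]]
            if not members:
                raise AlignmentError(
                    f"data set {code}: no regions of compartment {spec['compartment']}"
                )
        else:
            missing = [n for n in spec["regions"] if n not in by_name]
            if missing:
                raise MissingSampleError(f"data set {code}: regions missing: {missing}")
            members = [by_name[n] for n in spec["regions"]]
        datasets[code] = concatenate_regions(members, code, pad_missing=pad_missing)
    return datasets


def read_dataset_definitions(path: str | Path) -> dict[str, dict]:
    with open(path) as fh:
        defs = yaml.safe_load(fh)
    if not isinstance(defs, dict):
        raise FormatError(f"{path}: expected a mapping code -> definition")
    for code, spec in defs.items():
        if not isinstance(spec, dict) or not ({"compartment", "regions"} & set(spec)):
            raise FormatError(f"{path}: definition for {code} needs 'compartment' or 'regions'")
    return defs


def write_dataset(dataset: ConcatenatedDataSet, directory: str | Path) -> None:
    """Write a data set as FASTA plus a partition TSV (1-based inclusive)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta_alignment(dataset.alignment, directory / f"dataset_{dataset.code}.fasta")
    rows = [
        {"region": name, "start": start + 1, "end": stop}
        for name, (start, stop) in dataset.partition_map.items()
    ]
    pd.DataFrame(rows).to_csv(
        directory / f"dataset_{dataset.code}.partitions.tsv", sep="\t", index=False
    )


def read_dataset(directory: str | Path, code: str) -> ConcatenatedDataSet:
    directory = Path(directory)
    alignment = read_fasta_alignment(directory / f"dataset_{code}.fasta")
    part = pd.read_csv(directory / f"dataset_{code}.partitions.tsv", sep="\t")
    partition_map = {
        str(r.region): (int(r.start) - 1, int(r.end)) for r in part.itertuples()
    }
    return ConcatenatedDataSet(code=code, alignment=alignment, partition_map=partition_map)


def dataclass_to_dict(obj) -> dict:
    return dataclasses.asdict(obj)
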