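"""Readers and writers for the formats the pipeline touches.

VCF (via cyvcf2), sample->population TSV maps, local-ancestry tracts
(BED dialect and RFMix v2 ``.msp.tsv``), GFF3 gene annotation (via gffutils)
and BED output.  All coordinate conversion to the internal 0-based half-open
convention happens here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import (
    TRACT_COLUMNS,
    GeneRecord,
    GeneSet,
    HaplotypePanel,
    PanelError,
    PopulationMap,
    TractSet,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised on malformed input files."""


def read_phased_vcf(
    path: str | Path,
    region: str | None = None,
    drop_missing: bool = True,
) -> HaplotypePanel:
    """Read biallelic SNP records from a VCF into a :class:`HaplotypePanel`.

    Multiallelic records are dropped with a logged count.  Records with any
    missing genotype call are dropped when ``drop_missing`` (the expected
    input is imputed and phased, so these are edge cases).  If any
    heterozygous call is unphased the returned panel has ``phased=False``
    and haplotype statistics will refuse it.
    """
    from cyvcf2 import VCF

    if not Path(path).exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples (no GT field)")

    contigs, poss, refs, alts = [], [], [], []
    rows: list[np.ndarray] = []
    n_multi = n_missing = 0
    any_unphased_het = False
    it = vcf(region) if region else vcf
    for v in it:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gts = v.genotypes  # [[a0, a1, phased], ...]
        arr = np.array([g[:2] for g in gts], dtype=np.int16)
        if (arr < 0).any():
            n_missing += 1
            if drop_missing:
                continue
            raise FormatError(
                f"{path}: missing genotype at {v.CHROM}:{v.POS} "
                "(re-run with drop_missing=True to exclude such sites)"
            )
        if (arr > 1).any():
            n_multi += 1
            continue
        for g, a in zip(gts, arr):
            if a[0] != a[1] and not g[2]:
                any_unphased_het = True
        contigs.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(arr.reshape(-1))
    if n_multi:
        logger.warning("%s: dropped %d non-biallelic records", path, n_multi)
    if n_missing and drop_missing:
        logger.warning("%s: dropped %d records with missing calls", path, n_missing)
    if any_unphased_het:
        logger.warning("%s: unphased heterozygous calls; panel marked unphased", path)

    lengths = {}
    try:
        seqlens = vcf.seqlens
    except AttributeError:  # header lacks contig length declarations
        seqlens = []
    for name, ln in zip(vcf.seqnames, seqlens or []):
        lengths[name] = int(ln)
    mat = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    return HaplotypePanel(
        contig=np.array(contigs, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        haplotypes=mat,
        samples=samples,
        phased=not any_unphased_het,
        contig_lengths=lengths or None,
    )


def write_vcf(panel: HaplotypePanel, path: str | Path, meta: Sequence[str] = ()) -> None:
    """Write the panel as a phased VCF 4.2 file (GT only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bovscan\n")
        for line in meta:
            fh.write(f"##{line}\n")
        if panel.contig_lengths:
            for name, ln in panel.contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={ln}>\n")
        else:
            for name in panel.contigs:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        sep = "|" if panel.phased else "/"
        h = panel.haplotypes
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{h[2 * i, j]}{sep}{h[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{panel.contig[j]}\t{panel.pos[j]}\t.\t{panel.ref[j]}\t"
                f"{panel.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a two-column TSV ``sample<TAB>population`` (``#`` lines ignored)."""
    mapping = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected sample<TAB>population")
        mapping[parts[0]] = parts[1]
    return PopulationMap(mapping)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#sample\tpopulation\n")
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# ancestry tracts
# ---------------------------------------------------------------------------


def read_tracts(path: str | Path, dialect: str = "bed") -> TractSet:
    """Read local-ancestry tracts.

    ``dialect="bed"`` expects ``contig start end sample hap donor [prob]``
    per line; ``dialect="rfmix-msp"`` parses an RFMix v2 ``.msp.tsv`` file,
    emitting one tract per run of constant ancestry per haplotype.
    """
    if dialect == "bed":
        return _read_tracts_bed(path)
    if dialect == "rfmix-msp":
        return _read_tracts_msp(path)
    raise ValueError(f"unknown tract dialect {dialect!r}")


def _read_tracts_bed(path: str | Path) -> TractSet:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise FormatError(
                f"{path}:{lineno}: expected >=6 tab-separated fields "
                "(contig start end sample hap donor [prob])"
            )
        try:
            rec = dict(
                contig=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
                sample=parts[3],
                hap=int(parts[4]),
                donor=parts[5],
                prob=float(parts[6]) if len(parts) > 6 else 1.0,
            )
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: {e}") from None
        records.append(rec)
    return TractSet(pd.DataFrame(records, columns=TRACT_COLUMNS))


def _read_tracts_msp(path: str | Path) -> TractSet:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated msp file")
    code_map = {}
    first = lines[0]
    if not first.startswith("#Subpopulation order/codes:"):
        raise FormatError(f"{path}:1: expected '#Subpopulation order/codes:' line")
    for tok in first.split(":", 1)[1].replace("\t", " ").split():
        if "=" in tok:
            name, code = tok.rsplit("=", 1)
            code_map[int(code)] = name
    header = lines[1].lstrip("#").split("\t")
    hap_cols = header[6:]
    if not hap_cols:
        raise FormatError(f"{path}:2: no haplotype columns in msp header")
    # hap columns are named sample.0 / sample.1
    hap_ids = []
    for col in hap_cols:
        sample, _, hap = col.rpartition(".")
        if hap not in ("0", "1"):
            raise FormatError(f"{path}:2: bad haplotype column name {col!r}")
        hap_ids.append((sample, int(hap)))

    records = []
    open_tracts: dict[int, list] = {}  # col index -> [contig, start, end, code]
    prev_contig = None
    for lineno, line in enumerate(lines[2:], 3):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6 + len(hap_cols):
            raise FormatError(f"{path}:{lineno}: expected {6 + len(hap_cols)} fields")
        contig, spos, epos = parts[0], int(parts[1]), int(parts[2])
        codes = [int(x) for x in parts[6:]]
        if contig != prev_contig:
            records.extend(_flush_msp(open_tracts, hap_ids, code_map))
            open_tracts = {}
            prev_contig = contig
        for k, code in enumerate(codes):
            cur = open_tracts.get(k)
            if cur is not None and cur[3] == code and cur[2] == spos:
                cur[2] = epos
            else:
                if cur is not None:
                    records.extend(_flush_msp({k: cur}, hap_ids, code_map))
                open_tracts[k] = [contig, spos, epos, code]
    records.extend(_flush_msp(open_tracts, hap_ids, code_map))
    return TractSet(pd.DataFrame(records, columns=TRACT_COLUMNS))


def _flush_msp(open_tracts, hap_ids, code_map):
    for k in sorted(open_tracts):
        contig, start, end, code = open_tracts[k]
        sample, hap = hap_ids[k]
        yield dict(
            contig=contig,
            start=start,
            end=end,
            sample=sample,
            hap=hap,
            donor=code_map.get(code, str(code)),
            prob=1.0,
        )


def write_tracts_bed(
    tracts: TractSet, path: str | Path, meta: Sequence[str] = ()
) -> None:
    """Write tracts in the BED dialect ``contig start end sample hap donor prob``."""
    with Path(path).open("w") as fh:
        for line in meta:
            fh.write(f"#{line}\n")
        fh.write("#contig\tstart\tend\tsample\thap\tdonor\tprob\n")
        for row in tracts.df.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.start}\t{row.end}\t{row.sample}\t"
                f"{row.hap}\t{row.donor}\t{row.prob:g}\n"
            )


def write_bed(
    regions: Iterable[tuple[str, int, int]], path: str | Path, meta: Sequence[str] = ()
) -> None:
    """Write plain 3-column BED regions with ``#`` header metadata."""
    with Path(path).open("w") as fh:
        for line in meta:
            fh.write(f"#{line}\n")
        for contig, start, end in regions:
            fh.write(f"{contig}\t{start}\t{end}\n")


def read_bed_regions(path: str | Path) -> list[tuple[str, int, int]]:
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 BED fields")
        regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path, feature_type: str = "gene") -> GeneSet:
    """Parse gene records from GFF3 into 0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        name = (
            feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("gene", [None])[0]
            or feat.id
        )
        genes.append(
            GeneRecord(
                contig=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand or ".",
                name=name,
            )
        )
    return GeneSet(genes)
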