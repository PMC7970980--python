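"""File formats, bundled fixtures and FASTA conventions.

Tabular outputs are tab-separated UTF-8 with a header row and ``.`` for
missing values (bit-exact diffable).  FASTA headers use ``|``-separated
fields: panel references as ``>lineage|locus|allele_name`` and cohort
alleles as ``>specimenID|locus|tissue|alleleN|freq``.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seqs import IUPAC_CHARS, stable_rng
from .allelecall import CloneSet
from .errors import FastaFormatError, InputError, PackagingError
from .lineage import PanelEntry, ReferencePanel
from .simcohort import (
    ancestral_sequence,
    make_recombinant_cr,
    mutate_sequence,
    synthetic_reference_panel,
)

_DATA = resources.files("btnscreen") / "data"

#: sha256 of the bundled colony-count survey table (packaging integrity)
TABLE1_SHA256 = "2f87da1fa797d8a5163c6c10ee2fbc78f2b45ed28ddcc30547c7ac4ef9f1a02d"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file with validation.

    Raises :class:`FastaFormatError` listing offending records on duplicate
    ids or non-IUPAC characters; an empty file returns an empty list with a
    warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"no records in {path}", stacklevel=2)
        return []
    seen = set()
    duplicates = []
    bad_chars = []
    for rec in records:
        if rec.id in seen:
            duplicates.append(rec.id)
        seen.add(rec.id)
        if not set(str(rec.seq).upper()) <= IUPAC_CHARS:
            bad_chars.append(rec.id)
    if duplicates or bad_chars:
        problems = []
        if duplicates:
            problems.append(f"duplicate ids: {', '.join(duplicates)}")
        if bad_chars:
            problems.append(f"non-IUPAC characters in: {', '.join(bad_chars)}")
        raise FastaFormatError("; ".join(problems), records=duplicates + bad_chars)
    return records


def write_fasta(records, path) -> None:
    """Write records (SeqRecord or (id, sequence) pairs) as FASTA."""
    out = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            out.append(rec)
        else:
            rid, seq = rec
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


def parse_panel_header(header: str) -> tuple[str, str, str]:
    """Parse ``lineage|locus|allele_name`` from a panel FASTA id."""
    parts = header.lstrip(">").split("|")
    if len(parts) != 3:
        raise FastaFormatError(
            f"panel header must be lineage|locus|allele_name, got {header!r}"
        )
    return parts[0], parts[1], parts[2]


def load_reference_panel(path=None) -> ReferencePanel:
    """Load a reference panel FASTA (bundled synthetic stand-in by default)."""
    if path is None:
        path = _DATA / "reference_panel_synthetic.fasta"
        provenance = (
            "synthetic stand-in panel; see accessions.tsv for the GenBank "
            "namespace of the real reference alleles"
        )
    else:
        provenance = str(path)
    entries = []
    for rec in read_fasta(path):
        lineage, locus, name = parse_panel_header(rec.id)
        entries.append(PanelEntry(lineage, locus, name, str(rec.seq).upper()))
    return ReferencePanel(entries=entries, provenance=provenance)


# ---------------------------------------------------------------------------
# Bundled colony-count survey table (four diseased mussels J54..J181)


@dataclass
class Table1Fixture:
    """Colony counts from the bundled cloning survey of four diseased
    mussels (J54, J111, J161, J181) and their printed allele frequencies.

    ``rows``: one row per (individual, locus, tissue, allele) with the
    colony count among major sequences, the major and total clone counts of
    the experiment, the frequency as printed in the source table, and the
    detection method (cloning vs direct sequencing).
    """

    rows: pd.DataFrame

    def experiments(self):
        cloned = self.rows[self.rows.method == "cloning"]
        return list(cloned.groupby(["individual", "locus", "tissue"]).groups)

    def counts(self, individual, locus, tissue) -> dict[str, int]:
        sel = self.rows[
            (self.rows.individual == individual)
            & (self.rows.locus == locus)
            & (self.rows.tissue == tissue)
            & (self.rows.method == "cloning")
        ]
        return dict(zip(sel.allele, sel.colony_count.astype(int)))

    def totals(self, individual, locus, tissue) -> tuple[int, int]:
        sel = self.rows[
            (self.rows.individual == individual)
            & (self.rows.locus == locus)
            & (self.rows.tissue == tissue)
            & (self.rows.method == "cloning")
        ]
        if sel.empty:
            raise InputError(f"no cloning experiment {individual}/{locus}/{tissue}")
        return int(sel.total_major.iloc[0]), int(sel.total_all.iloc[0])

    def direct_alleles(self, individual, locus, tissue) -> list[str]:
        sel = self.rows[
            (self.rows.individual == individual)
            & (self.rows.locus == locus)
            & (self.rows.tissue == tissue)
            & (self.rows.method == "direct")
        ]
        return list(sel.allele)


def load_table1() -> Table1Fixture:
    """Load the bundled survey table, verifying packaging integrity."""
    path = _DATA / "table1.tsv"
    try:
        raw = path.read_bytes()
    except FileNotFoundError as exc:  # pragma: no cover
        raise PackagingError("table1.tsv missing from package data") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise PackagingError(
            f"table1.tsv checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"allele": str}, na_values=["."])
    # invariant: per-experiment counts sum to the major total
    for (ind, locus, tissue), grp in df[df.method == "cloning"].groupby(
        ["individual", "locus", "tissue"]
    ):
        if int(grp.colony_count.sum()) != int(grp.total_major.iloc[0]):
            raise PackagingError(
                f"counts do not sum to major total in {ind}/{locus}/{tissue}"
            )
        if int(grp.total_major.iloc[0]) > int(grp.total_all.iloc[0]):
            raise PackagingError(f"major > total in {ind}/{locus}/{tissue}")
    return Table1Fixture(rows=df)


def table1_sequences() -> dict[tuple[str, str], str]:
    """Deterministic synthetic sequences for every allele named in the
    bundled survey table.

    The sequences are a structural stand-in for the GenBank originals: the
    same name always maps to the same sequence, distinct names to distinct
    sequences, and the documented relationships hold — EF1α G/H are the
    BTN2 panel pair (21 substitutions apart), G1 is one substitution off G,
    D and 7 differ by a single swap at the 5' end of the 9 bp poly-A tract,
    COI 1/2 are 6 substitutions apart, CR 1/2 are recombinant and highly
    divergent, CR 1' is three substitutions off CR-1.
    """
    panel = {(e.lineage, e.locus, e.allele_name): e.sequence
             for e in synthetic_reference_panel()}
    seqs: dict[tuple[str, str], str] = {}

    # EF1a ---------------------------------------------------------------
    ef_anc = ancestral_sequence("EF1a")
    seqs[("EF1a", "G")] = panel[("BTN2", "EF1a", "G")]
    seqs[("EF1a", "H")] = panel[("BTN2", "EF1a", "H")]
    g = seqs[("EF1a", "G")]
    # G1: one substitution off G, away from the poly-A tract
    g1 = list(g)
    g1[50] = "A" if g[50] != "A" else "C"
    seqs[("EF1a", "G1")] = "".join(g1)
    # D carries the ancestral poly-A context; 7 swaps the base 5' of the run
    d = mutate_sequence(ef_anc, 5, stable_rng("table1/EF1a/D"))
    d = d[:295] + ef_anc[295:311] + d[311:]  # keep the tract context ancestral
    seqs[("EF1a", "D")] = d
    seven = d[:299] + "A" + d[300:]
    seqs[("EF1a", "7")] = seven
    for name in ("1", "2", "3", "4", "5", "6", "8", "9"):
        for salt in range(100):
            cand = mutate_sequence(ef_anc, 6, stable_rng(f"table1/EF1a/{name}", salt))
            cand = cand[:295] + ef_anc[295:311] + cand[311:]
            if cand not in seqs.values():
                break
        seqs[("EF1a", name)] = cand

    # COI ----------------------------------------------------------------
    coi_b = panel[("BTN2", "COI", "B")]
    rng = stable_rng("table1/COI/cancer")
    shared = rng.choice(len(coi_b), size=10, replace=False)
    from ._seqs import substitute as _subst

    # 4 shared + 2 private subs give COI-1, 4 more private give COI-2:
    # d(1,B)=6, d(2,B)=8, d(1,2)=6, matching the recorded divergences
    common = _subst(coi_b, shared[:4], stable_rng("table1/COI/shared"))
    coi_1 = _subst(common, shared[4:6], stable_rng("table1/COI/c1"))
    coi_2 = _subst(common, shared[6:10], stable_rng("table1/COI/c2"))
    seqs[("COI", "1")] = coi_1
    seqs[("COI", "2")] = coi_2
    coi_f = panel[("host_F", "COI", "F")]
    for name in ("3", "4", "5", "6"):
        seqs[("COI", name)] = mutate_sequence(
            coi_f, 4, stable_rng(f"table1/COI/{name}")
        )

    # CR -----------------------------------------------------------------
    cr_f = panel[("host_F", "CR", "F")]
    cr_m = panel[("host_M", "CR", "M")]
    cr_1 = make_recombinant_cr(
        mutate_sequence(cr_f, 4, stable_rng("table1/CR/1f")),
        mutate_sequence(cr_m, 3, stable_rng("table1/CR/1m")),
        (200, 400),
    )
    cr_2 = make_recombinant_cr(
        mutate_sequence(cr_f, 6, stable_rng("table1/CR/2f")),
        mutate_sequence(cr_m, 5, stable_rng("table1/CR/2m")),
        (200, 400),
    )
    seqs[("CR", "1")] = cr_1
    seqs[("CR", "1'")] = mutate_sequence(cr_1, 3, stable_rng("table1/CR/1p"))
    seqs[("CR", "2")] = cr_2
    for name in ("3", "4", "5", "6"):
        seqs[("CR", name)] = mutate_sequence(
            cr_f, 4, stable_rng(f"table1/CR/{name}")
        )
    return seqs


def table1_clone_sets(
    fixture: Table1Fixture | None = None,
    sequences: dict[tuple[str, str], str] | None = None,
) -> list[CloneSet]:
    """Reconstruct the colony sets of every cloning experiment in the
    bundled survey table.

    Major-sequence colonies replicate the recorded counts; the difference
    between the total and major clone counts is realized as singleton
    artifact colonies, each carrying a 1–2 substitution mutant unique
    across the whole study (so the singleton-exclusion rule removes exactly
    those).
    """
    fixture = fixture or load_table1()
    sequences = sequences or table1_sequences()
    all_real = set(sequences.values())
    forbidden = set(all_real)
    clone_sets = []
    for ind, locus, tissue in fixture.experiments():
        counts = fixture.counts(ind, locus, tissue)
        total_major, total_all = fixture.totals(ind, locus, tissue)
        colonies = []
        c = 0
        for allele, cnt in counts.items():
            seq = sequences[(locus, allele)]
            for _ in range(cnt):
                c += 1
                colonies.append((f"c{c:02d}", seq))
        art_rng = stable_rng(f"table1-artifacts/{ind}/{locus}/{tissue}")
        first_seq = sequences[(locus, next(iter(counts)))]
        for _ in range(total_all - total_major):
            while True:
                mutant = mutate_sequence(
                    first_seq, int(art_rng.integers(1, 3)), art_rng
                )
                if mutant not in forbidden:
                    break
            forbidden.add(mutant)
            c += 1
            colonies.append((f"c{c:02d}", mutant))
        clone_sets.append(
            CloneSet(individual_id=ind, locus=locus, tissue=tissue, colonies=colonies)
        )
    return clone_sets


def load_accession_manifest() -> pd.DataFrame:
    """GenBank accession namespace for the real reference alleles (data
    only; nothing is ever fetched)."""
    path = _DATA / "accessions.tsv"
    return pd.read_csv(path, sep="\t")


def write_panel_fasta(path: str | Path) -> None:
    """Write the synthetic reference panel using the header convention."""
    records = [
        (f"{e.lineage}|{e.locus}|{e.allele_name}", e.sequence)
        for e in synthetic_reference_panel()
    ]
    write_fasta(records, path)


# ---------------------------------------------------------------------------
# Tabular serialization (tab-separated, UTF-8, header row, "." for missing)


def write_clone_sets(clone_sets, path) -> None:
    rows = [
        {
            "individual": cs.individual_id,
            "locus": cs.locus,
            "tissue": cs.tissue,
            "colony_id": cid,
            "sequence": seq,
        }
        for cs in clone_sets
        for cid, seq in cs.colonies
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clone_sets(path) -> list[CloneSet]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for (ind, locus, tissue), grp in df.groupby(
        ["individual", "locus", "tissue"], sort=False
    ):
        out.append(
            CloneSet(
                individual_id=ind,
                locus=locus,
                tissue=tissue,
                colonies=list(zip(grp.colony_id, grp.sequence)),
            )
        )
    return out


def write_genotypes(genotypes, path) -> None:
    from .allelecall import TissueGenotype  # noqa: F401 (documented type)

    rows = [
        {
            "individual": gt.individual_id,
            "locus": gt.locus,
            "tissue": gt.tissue,
            "allele_id": a.allele_id,
            "sequence": a.sequence,
            "colony_count": a.colony_count,
            "frequency": f"{a.frequency:.6f}",
            "status": a.status,
        }
        for gt in genotypes
        for a in gt.alleles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotypes(path):
    from .allelecall import AlleleCall, TissueGenotype, ARTIFACT_EXCLUDED

    df = pd.read_csv(path, sep="\t", dtype={"allele_id": str, "sequence": str})
    out = []
    for (ind, locus, tissue), grp in df.groupby(
        ["individual", "locus", "tissue"], sort=False
    ):
        alleles = [
            AlleleCall(
                allele_id=str(r.allele_id),
                sequence=r.sequence,
                colony_count=int(r.colony_count),
                frequency=float(r.frequency),
                status=r.status,
            )
            for r in grp.itertuples()
        ]
        retained = [a for a in alleles if a.status != ARTIFACT_EXCLUDED]
        out.append(
            TissueGenotype(
                individual_id=ind,
                locus=locus,
                tissue=tissue,
                alleles=alleles,
                heteroplasmic=(locus in ("COI", "CR", "16S") and len(retained) > 1),
            )
        )
    return out


def write_flow_events(eventset, path) -> None:
    """One-column numeric text; header row carries the specimen id."""
    with open(path, "w") as fh:
        fh.write(f"{eventset.specimen_id}\n")
        for x in eventset.intensities:
            fh.write(f"{x:.6f}\n")


def read_flow_events(path):
    from .flowploidy import FlowEventSet
    import numpy as np

    with open(path) as fh:
        specimen_id = fh.readline().strip()
        values = np.loadtxt(fh, dtype=float, ndmin=1)
    return FlowEventSet(specimen_id=specimen_id, intensities=values)


def write_cohort_truth(cohort, path) -> None:
    cohort.truth.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


def write_cohort_fasta(cohort, out_dir) -> None:
    """Per-locus multi-FASTA with ``>specimenID|locus|tissue|alleleN|freq``."""
    out = Path(out_dir)
    loci = sorted({
        locus for sp in cohort.specimens for locus in sp.tissues["hemolymph"]
    })
    for locus in loci:
        records = []
        for sp in cohort.specimens:
            for tissue, by_locus in sp.tissues.items():
                gt = by_locus.get(locus)
                if gt is None:
                    continue
                for k, a in enumerate(gt.retained(), 1):
                    records.append(
                        (
                            f"{sp.id}|{locus}|{tissue}|allele{k}|{a.frequency:.4f}",
                            a.sequence,
                        )
                    )
        write_fasta(records, out / f"cohort_{locus}.fasta")


def table1_genotypes(merge_homopolymers: bool = True):
    """Per-individual tissue genotypes reconstructed from the bundled
    survey table: cloning experiments are re-called (with cross-reference
    rescue) and direct-sequencing rows are expanded into dominant/minority
    genotypes using the piggyback convention (in hemolymph the dominant
    chromatogram signal is the allele absent from the foot).

    Returns ``individual -> locus -> tissue -> TissueGenotype``.
    """
    from . import allelecall

    fixture = load_table1()
    sequences = table1_sequences()
    clone_sets = table1_clone_sets(fixture, sequences)
    names = {(locus, seq): name for (locus, name), seq in sequences.items()}
    namer = allelecall.AlleleNamer(references=names)

    out: dict[str, dict[str, dict[str, object]]] = {}
    for cs in clone_sets:
        gt = allelecall.call_alleles(cs, cross_reference=clone_sets, namer=namer)
        if merge_homopolymers:
            gt = allelecall.merge_homopolymer_variants(gt)
        out.setdefault(cs.individual_id, {}).setdefault(cs.locus, {})[cs.tissue] = gt

    def direct_gt(ind, locus, tissue, weighted):
        alleles = [
            allelecall.AlleleCall(
                allele_id=name,
                sequence=sequences[(locus, name)],
                colony_count=0,
                frequency=freq,
                status=allelecall.COMMON if freq >= 0.5 else allelecall.RARE,
            )
            for name, freq in weighted
        ]
        return allelecall.TissueGenotype(
            individual_id=ind,
            locus=locus,
            tissue=tissue,
            alleles=alleles,
            heteroplasmic=len(alleles) > 1,
        )

    directs = fixture.rows[fixture.rows.method == "direct"]
    for (ind, locus, tissue), grp in directs.groupby(
        ["individual", "locus", "tissue"], sort=False
    ):
        alleles = list(grp.allele)
        if tissue == "foot" or len(alleles) == 1:
            weighted = [(alleles[0], 1.0)]
        else:
            foot = fixture.direct_alleles(ind, locus, "foot")
            minor = foot[0] if foot and foot[0] in alleles else alleles[-1]
            major = next(a for a in alleles if a != minor)
            weighted = [(major, 0.8), (minor, 0.2)]
        out.setdefault(ind, {}).setdefault(locus, {})[tissue] = direct_gt(
            ind, locus, tissue, weighted
        )
    return out
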