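"""Readers and writers: model JSON/SBML, MGE composition, media, provenance.

The model JSON dialect mirrors the community constraint-based schema
(id / metabolites / reactions with ``metabolites`` stoichiometry maps,
bounds, ``subsystem``, ``objective_coefficient``, ``gene_reaction_rule``),
so genome-scale models published in that dialect (e.g. BiGG's iJO1366.json)
load unchanged.  SBML parsing is delegated to COBRApy.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd
import yaml
from Bio import SeqIO

from .core import MetabolicModel, Metabolite, Reaction
from .errors import ConfigurationError, FormatError, ValidationError
from .mge import (AMINO_ACIDS, MgeGenomeSpec, MonomerTable, NUCLEOTIDES,
                  ProteinSpec)

_GENE_TOKEN = re.compile(r"[A-Za-z0-9_.\-]+")


def _gene_rules_from_reactions(reactions: List[Reaction]) -> Optional[Dict[str, List[str]]]:
    rules: Dict[str, List[str]] = {}
    for r in reactions:
        for tok in _GENE_TOKEN.findall(r.gene_reaction_rule):
            if tok in ("and", "or", "AND", "OR"):
                continue
            rules.setdefault(tok, []).append(r.id)
    return rules or None


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: float(v) for k, v in sorted(r.stoichiometry.items())},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "subsystem": r.subsystem,
                "gene_reaction_rule": r.gene_reaction_rule,
                "objective_coefficient": model.objective.get(r.id, 0),
                "notes": {"is_exchange": r.is_exchange,
                          "is_pseudoreaction": r.is_pseudoreaction},
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in sorted(model.gene_rules)] if model.gene_rules else [],
    }


def write_model(model: MetabolicModel, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=False) + "\n")


def _looks_like_exchange(rxn_id: str, stoich: Dict[str, float]) -> bool:
    return len(stoich) == 1 and (rxn_id.startswith("EX_") or rxn_id.startswith("DM_")
                                 or rxn_id.startswith("SK_"))


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        mets = [Metabolite(id=m["id"], name=m.get("name", ""),
                           compartment=m.get("compartment", "c") or "c")
                for m in data["metabolites"]]
        reactions = []
        objective: Dict[str, float] = {}
        for r in data["reactions"]:
            stoich = {k: float(v) for k, v in r["metabolites"].items()}
            notes = r.get("notes", {}) or {}
            is_ex = bool(notes.get("is_exchange",
                                   _looks_like_exchange(r["id"], stoich)))
            rxn = Reaction(
                id=r["id"], name=r.get("name", ""), stoichiometry=stoich,
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                subsystem=r.get("subsystem", "") or "",
                gene_reaction_rule=r.get("gene_reaction_rule", "") or "",
                is_exchange=is_ex,
                is_pseudoreaction=bool(notes.get("is_pseudoreaction", False)),
            )
            reactions.append(rxn)
            w = float(r.get("objective_coefficient", 0) or 0)
            if w:
                objective[r["id"]] = w
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed model JSON: {exc!r}") from exc
    model = MetabolicModel(metabolites=mets, reactions=reactions,
                           objective=objective,
                           gene_rules=_gene_rules_from_reactions(reactions),
                           id=data.get("id", "model"))
    model.validate()
    return model


def from_cobra(cobra_model) -> MetabolicModel:
    """Convert a COBRApy model to the package's container."""
    mets = [Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
            for m in cobra_model.metabolites]
    reactions = []
    objective: Dict[str, float] = {}
    for r in cobra_model.reactions:
        reactions.append(Reaction(
            id=r.id, name=r.name or "",
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound), upper_bound=float(r.upper_bound),
            subsystem=r.subsystem or "",
            gene_reaction_rule=r.gene_reaction_rule or "",
            is_exchange=len(r.metabolites) == 1 and r in cobra_model.boundary,
        ))
        w = float(r.objective_coefficient)
        if w:
            objective[r.id] = w
    return MetabolicModel(metabolites=mets, reactions=reactions, objective=objective,
                          gene_rules=_gene_rules_from_reactions(reactions),
                          id=cobra_model.id or "model")


def to_cobra(model: MetabolicModel):
    """Convert to a COBRApy model (used for independent cross-checks)."""
    import cobra

    cm = cobra.Model(model.id)
    cmets = {m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
             for m in model.metabolites}
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cmets[mid]: c for mid, c in r.stoichiometry.items()})
    cm.objective = {cm.reactions.get_by_id(rid): w for rid, w in model.objective.items()}
    return cm


def read_model(path: Union[str, Path], dialect: Optional[str] = None) -> MetabolicModel:
    """Load a model from JSON (native) or SBML (via COBRApy)."""
    path = Path(path)
    if dialect is None:
        dialect = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if dialect == "json":
        try:
            data = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        return model_from_dict(data)
    if dialect == "sbml":
        try:
            import cobra
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # cobra raises a zoo of parse errors
            raise FormatError(f"cannot parse SBML {path}: {exc}") from exc
        return from_cobra(cm)
    raise ConfigurationError(f"unknown model dialect {dialect!r}")


# ---------------------------------------------------------------------------
# MGE composition


def read_mge_spec(genome_fasta: Optional[Union[str, Path]] = None,
                  proteins_fasta: Optional[Union[str, Path]] = None,
                  copies_tsv: Optional[Union[str, Path]] = None,
                  yaml_path: Optional[Union[str, Path]] = None,
                  strandedness: str = "dsDNA", copy_number: int = 1,
                  ) -> Tuple[MgeGenomeSpec, List[ProteinSpec]]:
    """Load an MGE composition either from FASTA+TSV files or a YAML spec.

    FASTA route: ``genome_fasta`` holds the genome (first record = packaged
    strand, further records = replication intermediates); ``proteins_fasta``
    one record per protein; ``copies_tsv`` columns ``protein_id`` and
    ``copy_number``.  YAML route: a single document with ``genome:`` and
    ``proteins:`` sections embedding sequences and copies.
    """
    if yaml_path is not None:
        data = yaml.safe_load(Path(yaml_path).read_text())
        try:
            g = data["genome"]
            genome = MgeGenomeSpec(
                sequence=g["sequence"],
                strandedness=g.get("strandedness", "dsDNA"),
                copy_number=int(g.get("copy_number", 1)),
                intermediates=tuple(g.get("intermediates", []) or ()),
            )
            proteome = [ProteinSpec(protein_id=p["id"], sequence=p["sequence"],
                                    copy_number=int(p.get("copy_number", 1)))
                        for p in data.get("proteins", []) or []]
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed MGE YAML spec: {exc!r}") from exc
        genome.validate()
        for p in proteome:
            p.validate()
        return genome, proteome

    if genome_fasta is None:
        raise ConfigurationError("either yaml_path or genome_fasta is required")
    records = list(SeqIO.parse(str(genome_fasta), "fasta"))
    if not records:
        raise FormatError(f"no records in genome FASTA {genome_fasta}")
    genome = MgeGenomeSpec(sequence=str(records[0].seq).upper(),
                           strandedness=strandedness, copy_number=copy_number,
                           intermediates=tuple(str(r.seq).upper() for r in records[1:]))
    genome.validate()

    proteome: List[ProteinSpec] = []
    if proteins_fasta is not None:
        prot_records = list(SeqIO.parse(str(proteins_fasta), "fasta"))
        copies: Dict[str, int] = {}
        if copies_tsv is not None:
            df = pd.read_csv(copies_tsv, sep="\t")
            for col in ("protein_id", "copy_number"):
                if col not in df.columns:
                    raise FormatError(f"copy-number TSV lacks column {col!r}")
            copies = dict(zip(df["protein_id"].astype(str), df["copy_number"].astype(int)))
        for rec in prot_records:
            if rec.id not in copies:
                raise ValidationError(
                    f"protein {rec.id!r} in FASTA has no copy number in the TSV")
            proteome.append(ProteinSpec(protein_id=rec.id,
                                        sequence=str(rec.seq).upper(),
                                        copy_number=copies[rec.id]))
        for p in proteome:
            p.validate()
    return genome, proteome


def write_mge_fasta_tsv(genome: MgeGenomeSpec, proteome: List[ProteinSpec],
                        genome_fasta: Union[str, Path],
                        proteins_fasta: Union[str, Path],
                        copies_tsv: Union[str, Path]) -> None:
    lines = [">genome", genome.sequence]
    for i, inter in enumerate(genome.intermediates, 1):
        lines += [f">intermediate_{i}", inter]
    Path(genome_fasta).write_text("\n".join(lines) + "\n")
    plines = []
    for p in proteome:
        plines += [f">{p.protein_id}", p.sequence]
    Path(proteins_fasta).write_text("\n".join(plines) + ("\n" if plines else ""))
    df = pd.DataFrame({"protein_id": [p.protein_id for p in proteome],
                       "copy_number": [p.copy_number for p in proteome]})
    df.to_csv(copies_tsv, sep="\t", index=False)


def read_monomer_table(path: Union[str, Path]) -> MonomerTable:
    """Optional YAML override of monomer masses / metabolite-id mapping."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    table = MonomerTable()
    for key in ("nucleotide_masses", "amino_acid_masses",
                "nucleotide_ids", "amino_acid_ids"):
        if key in data:
            getattr(table, key).update(data[key])
    for key in ("atp_id", "adp_id", "pi_id", "ppi_id", "h2o_id", "h_id"):
        if key in data:
            setattr(table, key, data[key])
    table.validate()
    return table


def read_media(path: Union[str, Path]) -> Dict[str, float]:
    """Media composition (metabolite id -> mmol) from YAML or 2-column TSV."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        data = yaml.safe_load(path.read_text()) or {}
        return {str(k): float(v) for k, v in data.items()}
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"media TSV {path} needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def pseudoreaction_table(spec, table: Optional[MonomerTable] = None) -> pd.DataFrame:
    """Human-readable stoichiometry table of a PseudoreactionSpec (mmol/g MGE)."""
    table = table or MonomerTable()
    rows = []
    for nt in NUCLEOTIDES:
        rows.append({"component": f"dNTP_{nt}", "metabolite": table.nucleotide_ids[nt],
                     "side": "reactant", "coefficient_mmol_per_g": spec.nucleotide_coeffs[nt]})
    for aa in AMINO_ACIDS:
        rows.append({"component": f"AA_{aa}", "metabolite": table.amino_acid_ids[aa],
                     "side": "reactant", "coefficient_mmol_per_g": spec.aa_coeffs[aa]})
    rows += [
        {"component": "ATP", "metabolite": table.atp_id, "side": "reactant",
         "coefficient_mmol_per_g": spec.atp_coeff},
        {"component": "H2O", "metabolite": table.h2o_id, "side": "reactant",
         "coefficient_mmol_per_g": spec.h2o_coeff},
        {"component": "ADP", "metabolite": table.adp_id, "side": "product",
         "coefficient_mmol_per_g": spec.adp_coeff},
        {"component": "Pi", "metabolite": table.pi_id, "side": "product",
         "coefficient_mmol_per_g": spec.pi_coeff},
        {"component": "H+", "metabolite": table.h_id, "side": "product",
         "coefficient_mmol_per_g": spec.h_coeff},
        {"component": "PPi", "metabolite": table.ppi_id, "side": "product",
         "coefficient_mmol_per_g": spec.ppi_coeff},
    ]
    return pd.DataFrame(rows, columns=["component", "metabolite", "side",
                                       "coefficient_mmol_per_g"])


def write_provenance(out_dir: Union[str, Path], config: dict,
                     seed: Optional[int] = None) -> Path:
    """Machine-readable run record: config hash, package/library versions, seed."""
    import numpy
    import scipy

    from . import __version__

    payload = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "versions": {"mgeburden": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__},
    }
    out = Path(out_dir) / "provenance.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n")
    return out
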