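"""Analysis subsets and within-cohort minor allele frequencies.

The filtering cascade needs internal allele frequencies computed on specific
sample subsets derived from the relatedness analysis:

* unrelated controls — the maximum unrelated set restricted to controls
  (the internal frequency reference for the rarity filter);
* all affected cases;
* unrelated index cases — exactly one case per family network.

MAF is computed from called genotypes only (missing genotypes drop out of
the allele number), folded to the minor allele, and male X genotypes
contribute a single allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["SubsetDefinition", "define_subsets", "compute_subset_maf", "annotate_subset_mafs"]


@dataclass
class SubsetDefinition:
    name: str
    members: list = field(default_factory=list)

    def __post_init__(self):
        self.members = list(self.members)
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"subset {self.name!r} has duplicate members")


def define_subsets(samples: pd.DataFrame, family_networks=(), unrelated_set=None):
    """Build the three analysis subsets from the sample sheet.

    ``samples`` needs columns ``sample_id`` and ``status`` ("case" or
    "control").  ``family_networks`` is an iterable of sample-id sets
    (connected components of the kinship graph); ``unrelated_set`` the
    maximum unrelated sample list (defaults to everyone, i.e. no
    relatedness information).  The index-case subset keeps one case per
    family network (the lexicographically first, for determinism).
    """
    status = samples.set_index("sample_id")["status"]
    if status.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample sheet")
    bad = set(status.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")
    cases = [s for s in samples["sample_id"] if status[s] == "case"]
    controls = [s for s in samples["sample_id"] if status[s] == "control"]
    unrelated = set(unrelated_set) if unrelated_set is not None else set(samples["sample_id"])

    in_network = {}
    for net in family_networks:
        net = set(net) & set(status.index)
        for s in net:
            in_network[s] = frozenset(net)
    index_cases, seen_networks = [], set()
    for s in cases:  # sample-sheet order, one per family network
        net = in_network.get(s)
        if net is None:
            index_cases.append(s)
        elif net not in seen_networks:
            seen_networks.add(net)
            index_cases.append(min(net & set(cases)))
    return [
        SubsetDefinition("unrelated_controls", [s for s in controls if s in unrelated]),
        SubsetDefinition("affected_cases", cases),
        SubsetDefinition("index_cases", index_cases),
    ]


def compute_subset_maf(
    genotypes: GenotypeMatrix,
    subset: SubsetDefinition,
    variants: pd.DataFrame,
    sex: pd.Series | None = None,
) -> pd.DataFrame:
    """Allele count / allele number / folded MAF per variant within a subset.

    ``variants`` supplies the ``is_x`` flag (row-aligned with genotype
    columns); ``sex`` maps sample_id -> "male"/"female" and is required when
    any variant is on X (males carry one allele there).  Sites with no
    called genotype in the subset get NaN MAF and ``maf_defined`` False —
    they are flagged, never dropped.
    """
    if not subset.members:
        raise ValueError(f"subset {subset.name!r} is empty")
    id_to_row = {s: i for i, s in enumerate(genotypes.sample_ids)}
    missing_ids = [s for s in subset.members if s not in id_to_row]
    if missing_ids:
        raise ValueError(f"subset members absent from genotypes: {missing_ids[:5]}")
    rows = np.array([id_to_row[s] for s in subset.members])
    is_x = variants["is_x"].to_numpy(dtype=bool)
    if is_x.any() and sex is None:
        raise ValueError("sex information required for X-chromosome MAF")
    male = np.zeros(rows.size, dtype=bool)
    if sex is not None:
        male = np.array([sex.get(s) == "male" for s in subset.members])

    if "row" in variants.columns:
        cols = variants["row"].to_numpy(dtype=int)
    else:
        cols = np.arange(genotypes.n_variants)
    if cols.size != len(variants):
        raise ValueError("variant table does not align with genotype columns")
    dos = genotypes.dosage[rows, :][:, cols]
    miss = genotypes.missing[rows, :][:, cols]
    ac = np.asarray(dos.sum(axis=0)).ravel().astype(float)
    n_missing = np.asarray(miss.sum(axis=0)).ravel().astype(float)
    n_called = rows.size - n_missing
    an = 2.0 * n_called
    if is_x.any():
        # males contribute one allele on X; subtract one per called male
        male_missing = np.asarray(miss[male, :].sum(axis=0)).ravel().astype(float)
        called_males = male.sum() - male_missing
        an = np.where(is_x, an - called_males, an)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, ac / an, np.nan)
    maf = np.minimum(af, 1.0 - af)
    out = pd.DataFrame({
        "allele_count": ac,
        "allele_number": an,
        "alt_af": af,
        "maf": maf,
        "maf_defined": an > 0,
    })
    out.index = variants.index
    return out


def annotate_subset_mafs(variants: pd.DataFrame, genotypes: GenotypeMatrix,
                         subsets, sex=None) -> pd.DataFrame:
    """Append one ``maf_<subset>`` column per subset to the annotation table."""
    out = variants.copy()
    for sub in subsets:
        maf = compute_subset_maf(genotypes, sub, variants, sex=sex)
        out[f"maf_{sub.name}"] = maf["maf"]
    return out
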