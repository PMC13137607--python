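"""Synthetic fixtures: molecule sets, toy pockets, toy denoisers.

Everything is generated programmatically from a packaged SMILES list
and seeded random-number generators, so no external data is needed.
The toy denoisers stand in for a trained clean-sample predictor and
make guided-vs-unguided sampling experiments possible at desk scale.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import ELEMENT_VDW_DEFAULTS, LigandGraph, PocketStructure
from .guidance import DenoiserContract

__all__ = ["FIXTURE_SMILES", "make_fixture_set", "make_toy_pocket",
           "make_toy_denoiser"]

#: Drug-like molecules spanning common functional groups, ring systems
#: and heteroatoms; every entry types cleanly under MMFF94.
FIXTURE_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",                      # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                 # ibuprofen
    "CN1C=NC2=C1C(=O)N(C(=O)N2C)C",               # caffeine
    "CC(=O)Nc1ccc(O)cc1",                         # paracetamol
    "c1ccc2c(c1)cccn2",                           # quinoline
    "OC(=O)c1ccccc1O",                            # salicylic acid
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",                 # procainamide
    "CC(N)Cc1ccccc1",                             # amphetamine
    "NC(=O)c1ccc[nH]1",                           # pyrrole amide
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",               # naproxen
    "Clc1ccccc1C(=O)NCCN",                        # chlorobenzamide amine
    "CC1=CC(=O)C=CC1=O",                          # methylquinone
    "OCC1OC(O)C(O)C(O)C1O",                       # glucose
    "CN(C)CCOC(c1ccccc1)c1ccccc1",                # diphenhydramine
    "CC(=O)NC1=CC=C(C=C1)S(=O)(=O)N",             # sulfa amide
    "Fc1ccc(cc1)C(=O)CCCN1CCC(O)CC1",             # haloperidol fragment
    "CCOC(=O)C1=CC=CC=C1N",                       # benzocaine analogue
    "CSCCC(N)C(=O)O",                             # methionine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",                # tryptophan
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",                 # citric acid
    "C1CCC(CC1)NC(=O)C2=CC=CC=C2",                # cyclohexyl benzamide
    "CC(C)NCC(O)COc1ccccc1",                      # propranolol fragment
    "Brc1ccc(cc1)C(=O)O",                         # bromobenzoic acid
    "O=C(Nc1ccccc1)c1ccccc1",                     # benzanilide
    "CN1CCC(CC1)c1ccccc1",                        # phenylpiperidine
    "OCCN1CCN(CC1)c1ccccc1",                      # phenylpiperazine ethanol
    "CC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C",  # steroid core
    "Nc1ncnc2[nH]cnc12",                          # adenine
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                 # theobromine isomer
    "OC(=O)c1cc(O)c(O)c(O)c1",                    # gallic acid
    "CC(C)(C)NCC(O)c1ccc(O)c(O)c1",               # salbutamol fragment
    "Ic1ccc(cc1)C(=O)O",                          # iodobenzoic acid
    "OCC(O)C(O)C(O)C(O)CO",                       # sorbitol
    "CCOP(=O)(OCC)Oc1ccccc1",                     # phosphate triester
    "CSc1ccccc1N",                                # thioanisole amine
    "O=S(=O)(N)c1ccc(N)cc1",                      # sulfanilamide
    "CC1CCCCN1C",                                 # dimethylpiperidine
    "c1ccc(cc1)C2CCCN2",                          # phenylpyrrolidine
    "OC(c1ccccc1)c1ccccc1",                       # benzhydrol
    "N#Cc1ccccc1C(=O)O",                          # cyanobenzoic acid
    "CC#CCO",                                     # butynol
    "OCc1ccco1",                                  # furfuryl alcohol
    "OCc1cccs1",                                  # thiophene methanol
    "NC(=O)C1CCCN1",                              # prolinamide
    "CC(O)c1ccc(F)cc1",                           # fluorophenyl ethanol
    "ClCC(=O)Nc1ccccc1",                          # chloroacetanilide
    "CN(C)c1ccc(cc1)C=O",                         # DMAB aldehyde
    "C1CC2CCC1CC2",                               # bicyclooctane
    "OC1CCCC1c1ccccc1",                           # phenylcyclopentanol
    "CCOC(=O)c1cncc(C)c1",                        # pyridine ester
]


def make_fixture_set(n: int, seed: int = 0) -> list[LigandGraph]:
    """Deterministic set of 3D-embedded, explicit-H drug-like molecules.

    Cycles through the packaged SMILES list, embedding each with a seed
    derived from ``seed`` and the molecule index, so repeated calls with
    the same arguments return identical coordinates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out: list[LigandGraph] = []
    for idx in range(n):
        smi = FIXTURE_SMILES[idx % len(FIXTURE_SMILES)]
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        embed_seed = (seed * 100003 + 7919 * idx + 1) % (2**31 - 1)
        params = AllChem.ETKDGv3()
        params.randomSeed = embed_seed
        for attempt in range(5):
            if AllChem.EmbedMolecule(mol, params) == 0:
                break
            params.randomSeed = (embed_seed + 1 + attempt) % (2**31 - 1)
        else:
            raise RuntimeError(f"embedding failed for {smi}")
        graph = LigandGraph.from_rdkit(mol)
        graph.name = f"fixture-{idx:03d}"
        out.append(graph)
    return out


def make_toy_pocket(
    kind: str,
    seed: int = 0,
    n_atoms: int | None = None,
    radius: float | None = None,
    charges: np.ndarray | None = None,
) -> PocketStructure:
    """Small synthetic pockets (≤ 60 atoms) for cross-term experiments.

    ``point_charges`` — atoms scattered on a sphere with alternating
    charges; ``ring_cage`` — a neutral-ish carbon ring in the xy plane;
    ``shell`` — a distant spherical shell (default radius 15 Å), useful
    as a near-zero-interaction control.
    """
    rng = np.random.default_rng(seed)
    if kind == "point_charges":
        m = n_atoms or 8
        r = radius or 5.0
        coords = _sphere_points(m, r, rng, jitter=0.3)
        elements = ["O" if i % 2 else "N" for i in range(m)]
        q = np.where(np.arange(m) % 2, -0.3, 0.3).astype(float)
    elif kind == "ring_cage":
        m = n_atoms or 12
        r = radius or 6.0
        ang = 2 * np.pi * np.arange(m) / m
        coords = np.stack([r * np.cos(ang), r * np.sin(ang),
                           np.zeros(m)], axis=1)
        coords += 0.05 * rng.standard_normal(coords.shape)
        elements = ["C"] * m
        q = 0.05 * rng.standard_normal(m)
    elif kind == "shell":
        m = n_atoms or 40
        r = radius or 15.0
        coords = _sphere_points(m, r, rng, jitter=0.2)
        elements = ["C" if i % 3 else "O" for i in range(m)]
        q = 0.1 * rng.standard_normal(m)
    else:
        raise ValueError(f"unknown toy pocket kind {kind!r}")
    if charges is not None:
        q = np.asarray(charges, dtype=float)
        if len(q) != len(elements):
            raise ValueError("charges length mismatch")
    vdw = np.array([ELEMENT_VDW_DEFAULTS[e] for e in elements])
    return PocketStructure(
        coords=coords,
        elements=elements,
        partial_charges=q,
        vdw_epsilon=vdw[:, 1].copy(),
        vdw_rstar=vdw[:, 0].copy(),
        residue_ids=[f"T:TOY:{1 + i // 10}" for i in range(len(elements))],
    )


def _sphere_points(m: int, r: float, rng: np.random.Generator,
                   jitter: float) -> np.ndarray:
    v = rng.standard_normal((m, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r * v + jitter * rng.standard_normal((m, 3))


def make_toy_denoiser(
    kind: str,
    target: LigandGraph,
    seed: int = 0,
    noise_scale: float = 0.5,
    strain_scale: float = 0.25,
) -> DenoiserContract:
    """Toy clean-sample predictors standing in for a trained model.

    ``perfect`` always returns the target coordinates; ``noisy_target``
    returns the target plus noise that shrinks as t → 1 (deterministic
    in (X_t, t)); ``strained_target`` returns a fixed, deliberately
    strained conformer of the target — the substrate for guided versus
    unguided comparisons.
    """
    target_coords = target.coords.copy()

    if kind == "perfect":

        def denoiser(xt: LigandGraph, t: float, pocket=None) -> LigandGraph:
            return xt.with_coords(target_coords)

    elif kind == "noisy_target":

        def denoiser(xt: LigandGraph, t: float, pocket=None) -> LigandGraph:
            local = np.random.default_rng([seed, int(round(t * 1e6))])
            eps = local.standard_normal(target_coords.shape)
            return xt.with_coords(
                target_coords + (1.0 - t) * noise_scale * eps)

    elif kind == "strained_target":
        rng = np.random.default_rng(seed)
        strained = target_coords + strain_scale * rng.standard_normal(
            target_coords.shape)

        def denoiser(xt: LigandGraph, t: float, pocket=None) -> LigandGraph:
            return xt.with_coords(strained)

    else:
        raise ValueError(f"unknown toy denoiser kind {kind!r}")

    return denoiser
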