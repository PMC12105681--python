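import numpy as np
import pytest

import clusterpdf as cp


@pytest.fixture(scope="session")
def toy():
    """Default toy cluster (16 Ag + 2 Cl) with its channel map."""
    model, channel_map = cp.make_toy_cluster()
    return model, channel_map


@pytest.fixture(scope="session")
def rgrid():
    return cp.default_rgrid(16.0, 0.01)


@pytest.fixture()
def two_atom_model():
    return cp.ClusterModel(
        [
            cp.AtomSite("Ag", np.array([0.0, 0.0, 0.0]), label="Ag1"),
            cp.AtomSite("Ag", np.array([2.8, 0.0, 0.0]), label="Ag2"),
        ],
        name="pair",
    )


@pytest.fixture(scope="session")
def crystal_files(tmp_path_factory):
    """Synthetic PDB and mmCIF files: 16 Ag + 2 Cl HETATMs plus a few DNA atoms."""
    import gemmi

    root = tmp_path_factory.mktemp("structures")
    model, _ = cp.make_toy_cluster()

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(50, 50, 50, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    chain = gemmi.Chain("X")
    res = gemmi.Residue()
    res.name = "LIG"
    res.seqid = gemmi.SeqId(1, " ")
    res.het_flag = "H"
    for site in model.sites:
        atom = gemmi.Atom()
        atom.name = site.label
        atom.element = gemmi.Element(site.element)
        atom.pos = gemmi.Position(*(site.position + 25.0))
        res.add_atom(atom)
    chain.add_residue(res)
    gm.add_chain(chain)

    dna_chain = gemmi.Chain("A")
    rng = np.random.default_rng(7)
    for i, base in enumerate(["DA", "DC", "DG"], start=1):
        residue = gemmi.Residue()
        residue.name = base
        residue.seqid = gemmi.SeqId(i, " ")
        for j, el in enumerate(["C", "N", "O", "P"]):
            atom = gemmi.Atom()
            atom.name = f"{el}{j + 1}"
            atom.element = gemmi.Element(el)
            atom.pos = gemmi.Position(*(rng.uniform(0, 20, 3)))
            residue.add_atom(atom)
        dna_chain.add_residue(residue)
    gm.add_chain(dna_chain)
    st.add_model(gm)
    st.setup_entities()

    pdb_path = root / "toy.pdb"
    cif_path = root / "toy.cif"
    st.write_pdb(str(pdb_path))
    st.make_mmcif_document().write_file(str(cif_path))
    return {"pdb": pdb_path, "cif": cif_path, "model": model}


def brute_force_pdf(model, rgrid, sigma0=0.05, scale=1.0):
    """Independent oracle: explicit per-pair Gaussian sum (plain loops)."""
    import gemmi

    from clusterpdf.pdf_engine import truncated_gaussian

    pos = model.positions
    f = np.array([gemmi.Element(e).atomic_number for e in model.elements], float)
    fmean = f.mean()
    b = model.bisos
    total = np.zeros_like(rgrid)
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(pos[i] - pos[j])
            sigma = np.sqrt((b[i] + b[j]) / (8 * np.pi**2) + sigma0**2)
            w = f[i] * f[j] / fmean**2
            z2 = ((rgrid - d) / sigma) ** 2
            total += 2 * w * truncated_gaussian(z2) / (sigma * np.sqrt(2 * np.pi))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(rgrid > 0, scale * total / np.where(rgrid > 0, rgrid, 1.0), 0.0)
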