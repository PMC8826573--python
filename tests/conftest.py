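"""Shared fixtures: all inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from igface import contacts, orientation, structio, synthetic

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1      11.000  12.000  13.000  1.00  0.00           C\n"
    "END\n"
)

ALTLOC_PDB = (
    "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N\n"
    "ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.60  0.00           C\n"
    "ATOM      3  CA BSER A   1       2.000   0.000   0.000  0.40  0.00           C\n"
    "END\n"
)


@pytest.fixture(scope="session")
def toy_domain():
    return synthetic.build_toy_domain(7, 6, seed=0)


@pytest.fixture(scope="session")
def toy_domain_selection(toy_domain):
    last = max(a.resseq for a in toy_domain.atoms)
    return structio.DomainSelection("a", [("A", (1, last))])


@pytest.fixture(scope="session")
def complex_truth():
    """Assembled two-domain complex at a known orientation."""
    dom_a = synthetic.build_toy_domain(7, 6, seed=0)
    dom_b = synthetic.build_toy_domain(7, 6, seed=1, chain="B")
    return synthetic.assemble_complex(dom_a, dom_b, torsion=90.0, tilts=(70.0, 80.0), d_c=30.0)


@pytest.fixture(scope="session")
def complex_reference(complex_truth):
    cx, truth = complex_truth
    return orientation.build_reference(cx, truth.selections["a"], truth.selections["b"])


@pytest.fixture(scope="session")
def oracle_complex():
    """Compact complex (<500 atoms) with a real interface, for all-pairs
    oracle comparisons."""
    dom_a = synthetic.build_toy_domain(3, 4, seed=2)
    dom_b = synthetic.build_toy_domain(3, 4, seed=3, chain="B")
    return synthetic.assemble_complex(dom_a, dom_b, torsion=45.0, tilts=(70.0, 80.0), d_c=16.0)


@pytest.fixture(scope="session")
def small_traj():
    """Short noisy ensemble with one planted salt bridge (default spec plant)."""
    spec = synthetic.SynthSpec(n_frames=200, noise_sigma=0.3, seed=7)
    return synthetic.synthesize(spec)


@pytest.fixture(scope="session")
def small_traj_records(small_traj):
    traj, truth = small_traj
    roles = contacts.assign_chem_roles(traj.topology)
    idx_a = structio.select_domain(traj.topology, truth.selections["a"])
    idx_b = structio.select_domain(traj.topology, truth.selections["b"])
    records = contacts.contacts_over_trajectory(traj, roles, idx_a, idx_b)
    return traj, truth, records, idx_a, idx_b, roles


def minimal_pdb_file(tmp_path, text=MINIMAL_PDB, name="mini.pdb"):
    path = tmp_path / name
    path.write_text(text)
    return path
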