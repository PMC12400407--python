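import numpy as np
import pytest

from desmix.compositions import Composition
from desmix.toysim import BoxGeometry, build_random_config


@pytest.fixture
def equimolar_binary():
    return Composition(fractions={"HexA": 0.5, "IMID": 0.5})


@pytest.fixture
def cubic_box():
    return BoxGeometry.cubic(8.0)


@pytest.fixture
def random_mixture(equimolar_binary):
    """200-particle random equimolar HexA/IMID configuration."""
    return build_random_config(equimolar_binary, 200, 3.0, seed=42)


def brute_force_contacts(frame, cutoff):
    """All-pairs molecular contact counting (the reference oracle)."""
    box = frame.box
    species = frame.species.astype(str)
    mol = frame.molecule_ids
    n = frame.n_particles
    seen = set()
    counts = {}
    for i in range(n):
        for j in range(i + 1, n):
            if mol[i] == mol[j]:
                continue
            d = box.min_image(frame.coords[i] - frame.coords[j])
            if d @ d < cutoff * cutoff:
                pair = (min(mol[i], mol[j]), max(mol[i], mol[j]))
                if pair in seen:
                    continue
                seen.add(pair)
                key = tuple(sorted((species[i], species[j])))
                counts[key] = counts.get(key, 0) + 1
    return counts


@pytest.fixture
def contact_oracle():
    return brute_force_contacts
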