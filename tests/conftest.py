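import numpy as np
import pytest

import persistate as ps


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def short_design():
    return ps.TrialDesign(session_length=60.0)


def make_circular_trajectory(r=2.0, omega_deg=90.0, fps=60.0, n=600,
                             male_offset=(5.0, 0.0)):
    """Female on a circle of radius r, heading tangent; male stationary."""
    t = np.arange(n) / fps
    ang = np.radians(omega_deg) * t
    f_pos = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    f_head = np.column_stack([-np.sin(ang), np.cos(ang)])
    m_pos = np.tile(male_offset, (n, 1))
    m_head = np.tile([1.0, 0.0], (n, 1))
    return ps.Trajectory(f_pos=f_pos, m_pos=m_pos, f_head=f_head,
                         m_head=m_head, fps=fps)


@pytest.fixture
def circular_trajectory():
    return make_circular_trajectory()
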