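"""Dev-time: least-squares an idealized ribonucleotide template whose geometry
closes under the helix operator (twist 32.7 deg about z, rise 2.81 A).
Prints frozen coordinates for natrace.synthetic.
"""
import numpy as np
from scipy.optimize import least_squares

NAMES = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'", "O2'", "N9"]
IDX = {n: i for i, n in enumerate(NAMES)}

TWIST = np.deg2rad(32.7)
RISE = 2.81

def helix_op(x):
    c, s = np.cos(TWIST), np.sin(TWIST)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    return x @ R.T + np.array([0, 0, RISE])

# (a, b, target distance, weight)
DIST = [
    # ribose ring bonds
    ("C1'", "C2'", 1.53, 10), ("C2'", "C3'", 1.53, 10), ("C3'", "C4'", 1.53, 10),
    ("C4'", "O4'", 1.45, 10), ("O4'", "C1'", 1.41, 10),
    # ring 1-3 (angles)
    ("C1'", "C3'", 2.37, 5), ("C2'", "C4'", 2.39, 5), ("C3'", "O4'", 2.33, 5),
    ("C4'", "C1'", 2.35, 5), ("O4'", "C2'", 2.32, 5),
    # exocyclic bonds
    ("C2'", "O2'", 1.42, 10), ("C1'", "N9", 1.47, 10), ("C3'", "O3'", 1.42, 10),
    ("C4'", "C5'", 1.51, 10), ("C5'", "O5'", 1.42, 10), ("O5'", "P", 1.59, 10),
    ("P", "OP1", 1.48, 10), ("P", "OP2", 1.48, 10),
    # 1-3 / angle restraints
    ("OP1", "OP2", 2.52, 5), ("OP1", "O5'", 2.49, 5), ("OP2", "O5'", 2.49, 5),
    ("C4'", "O5'", 2.42, 5), ("C5'", "P", 2.61, 5), ("C3'", "C5'", 2.48, 5),
    ("C1'", "O2'", 2.41, 3), ("C3'", "O2'", 2.41, 3), ("C2'", "N9", 2.45, 3),
    ("O4'", "N9", 2.40, 3), ("C2'", "O3'", 2.41, 3), ("C4'", "O3'", 2.41, 3),
]
# distances to the NEXT nucleotide (helix image): chain closure O3'(i) -- P(i+1)
DIST_NEXT = [
    ("O3'", "P", 1.59, 20),      # covalent link
    ("O3'", "OP1", 2.49, 5), ("O3'", "OP2", 2.49, 5), ("O3'", "O5'", 2.49, 5),
    ("C3'", "P", 2.61, 5),
]
# soft positional anchors: (atom, target_radius, target_z, w_r, w_z)
ANCHOR = [
    ("C1'", 5.4, 0.0, 3.0, 0.5),
    ("P", 4.8, -2.0, 2.0, 0.5),
    ("N9", 3.9, 0.3, 2.0, 0.2),
    ("O2'", 6.4, 0.0, 0.5, 0.0),
]

def residuals(v):
    x = v.reshape(-1, 3)
    xn = helix_op(x)
    r = []
    for a, b, d, w in DIST:
        r.append(w * (np.linalg.norm(x[IDX[a]] - x[IDX[b]]) - d))
    for a, b, d, w in DIST_NEXT:
        r.append(w * (np.linalg.norm(x[IDX[a]] - xn[IDX[b]]) - d))
    for a, tr, tz, wr, wz in ANCHOR:
        p = x[IDX[a]]
        r.append(wr * (np.hypot(p[0], p[1]) - tr))
        if wz:
            r.append(wz * (p[2] - tz))
    # chirality/pucker nudge: keep O2' on opposite side of ring plane from C5'
    ring = x[[IDX[n] for n in ["C1'", "C2'", "C3'", "C4'", "O4'"]]]
    cen = ring.mean(0)
    nrm = np.cross(ring[1] - ring[0], ring[3] - ring[0])
    nrm = nrm / np.linalg.norm(nrm)
    s_c5 = np.dot(x[IDX["C5'"]] - cen, nrm)
    s_o2 = np.dot(x[IDX["O2'"]] - cen, nrm)
    s_n9 = np.dot(x[IDX["N9"]] - cen, nrm)
    r.append(2.0 * (s_c5 - 1.2))
    r.append(2.0 * (s_o2 + 1.2))
    r.append(2.0 * (s_n9 - 1.0))
    # ring centroid must sit inside the canonical 6 A view sphere
    r.append(3.0 * (np.hypot(cen[0], cen[1]) - 5.3))
    return np.array(r)

rng = np.random.default_rng(7)
best = None
for trial in range(40):
    # init: pentagon ring near radius 5.8, random-ish orientation
    ang0 = rng.uniform(0, 2 * np.pi)
    x0 = np.zeros((13, 3))
    th = np.deg2rad(90 + 72 * np.arange(5))
    ring0 = np.c_[1.27 * np.cos(th), 1.27 * np.sin(th), np.zeros(5)]
    # random rotation of ring
    from scipy.spatial.transform import Rotation
    R0 = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
    ring0 = ring0 @ R0.T + np.array([5.8, 0, 0])
    for k, n in enumerate(["C1'", "C2'", "C3'", "C4'", "O4'"]):
        x0[IDX[n]] = ring0[k]
    x0[IDX["O2'"]] = ring0[1] + [0.8, 0.8, -0.8]
    x0[IDX["N9"]] = ring0[0] + [-1.0, 0.3, 1.0]
    x0[IDX["O3'"]] = ring0[2] + [0.4, -0.9, -1.0]
    x0[IDX["C5'"]] = ring0[3] + [0.2, 0.5, 1.4]
    x0[IDX["O5'"]] = x0[IDX["C5'"]] + [-0.3, -0.9, 1.0]
    x0[IDX["P"]] = x0[IDX["O5'"]] + [-0.5, -1.2, 0.8]
    x0[IDX["OP1"]] = x0[IDX["P"]] + [1.2, -0.8, 0.3]
    x0[IDX["OP2"]] = x0[IDX["P"]] + [-1.4, -0.2, 0.5]
    res = least_squares(residuals, x0.ravel(), max_nfev=20000)
    if best is None or res.cost < best.cost:
        best = res
        print(trial, res.cost)

x = best.x.reshape(-1, 3)
xn = helix_op(x)
print("final cost", best.cost)
print("O3'-P(next):", np.linalg.norm(x[IDX["O3'"]] - xn[IDX["P"]]))
print("C1' radius:", np.hypot(*x[IDX["C1'"]][:2]))
print("C1'-C1' step:", np.linalg.norm(x[IDX["C1'"]] - xn[IDX["C1'"]]))
ring = [("C1'", "C2'"), ("C2'", "C3'"), ("C3'", "C4'"), ("C4'", "O4'"), ("O4'", "C1'")]
for a, b in ring:
    print(a, b, np.linalg.norm(x[IDX[a]] - x[IDX[b]]))
print("\nTEMPLATE = {")
for n in NAMES:
    p = x[IDX[n]]
    print(f'    "{n}": ({p[0]:.4f}, {p[1]:.4f}, {p[2]:.4f}),')
print("}")
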