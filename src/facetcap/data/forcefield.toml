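# facetcap reduced molecular-mechanics parameter set, version 0.1
#
# Functional forms: harmonic bonds E = k (r - r0)^2, harmonic angles
# E = k (theta - theta0)^2, cosine torsions E = k (1 + cos(n phi - phi0)),
# 12-6 Lennard-Jones with Lorentz-Berthelot combining, point-charge Coulomb.
# Nonbonded interactions use a 12 Å cutoff with a C1 switching window
# starting at 10 Å; 1-2 and 1-3 pairs are excluded and 1-4 pairs are scaled
# (Lennard-Jones by 1/2, Coulomb by 1/1.2, the Amber convention).
#
# This is an embedded, reduced Amber-class table covering only the residues
# Ser/Phe/Pro/Gln/Asn plus acetyl and amide caps, 3-site water, and
# uncharged Lennard-Jones metal sites for the FCC substrate (CHARMM-METAL
# style).  It follows the functional forms of Amber-family force fields but
# is NOT the published Amber99sb-ILDN / CHARMM-METAL / TIP3P parameter
# files; absolute energies are not comparable with runs using those sets.

[meta]
name = "facetcap-reduced-amber-class"
version = "0.1"
cutoff = 12.0          # Å
switch_start = 10.0    # Å
scale14_lj = 0.5
scale14_coulomb = 0.8333333333
combining_rule = "lorentz-berthelot"

# eps in kcal/mol, rmin2 = Rmin/2 in Å (sigma = 2 * rmin2 / 2^(1/6))
[atom_types]
N  = { eps = 0.1700, rmin2 = 1.8240 }
H  = { eps = 0.0157, rmin2 = 0.6000 }
CT = { eps = 0.1094, rmin2 = 1.9080 }
H1 = { eps = 0.0157, rmin2 = 1.3870 }
HC = { eps = 0.0157, rmin2 = 1.4870 }
HA = { eps = 0.0150, rmin2 = 1.4590 }
C  = { eps = 0.0860, rmin2 = 1.9080 }
CA = { eps = 0.0860, rmin2 = 1.9080 }
O  = { eps = 0.2100, rmin2 = 1.6612 }
OH = { eps = 0.2104, rmin2 = 1.7210 }
HO = { eps = 0.0000, rmin2 = 0.6000 }
OW = { eps = 0.1520, rmin2 = 1.7683 }
HW = { eps = 0.0000, rmin2 = 0.6000 }

# Uncharged metal Lennard-Jones sites (CHARMM-METAL-style surface term).
[atom_types.AU]
eps = 5.29
rmin2 = 1.4745

# k in kcal/mol/Å^2, r0 in Å
[bonds]
"CT-N"  = [337.0, 1.449]
"H-N"   = [434.0, 1.010]
"CT-CT" = [310.0, 1.526]
"CT-H1" = [340.0, 1.090]
"CT-HC" = [340.0, 1.090]
"C-CT"  = [317.0, 1.522]
"C-O"   = [570.0, 1.229]
"C-N"   = [490.0, 1.335]
"CT-OH" = [320.0, 1.410]
"HO-OH" = [553.0, 0.960]
"CA-CA" = [469.0, 1.400]
"CA-HA" = [367.0, 1.080]
"CA-CT" = [317.0, 1.510]
"HW-OW" = [450.0, 0.9572]

# k in kcal/mol/rad^2, theta0 in degrees; X-T-X entries are per-center
# fallbacks keyed on the middle atom's type
[angles]
"CT-N-C"   = [50.0, 121.9]
"CT-N-CT"  = [50.0, 118.0]
"CT-N-H"   = [38.0, 118.04]
"C-N-H"    = [30.0, 119.8]
"N-CT-C"   = [63.0, 110.1]
"CT-CT-N"  = [80.0, 109.7]
"C-CT-CT"  = [63.0, 111.1]
"CT-C-O"   = [80.0, 120.4]
"CT-C-N"   = [70.0, 116.6]
"N-C-O"    = [80.0, 122.9]
"CA-CT-CT" = [63.0, 114.0]
"CA-CA-CA" = [63.0, 120.0]
"HW-OW-HW" = [100.0, 104.52]
"X-CT-X"   = [50.0, 109.5]
"X-C-X"    = [70.0, 120.0]
"X-CA-X"   = [63.0, 120.0]
"X-N-X"    = [50.0, 120.0]
"X-OH-X"   = [55.0, 108.5]
"X-OW-X"   = [100.0, 104.52]

# each value is a list of [k (kcal/mol), n, phi0 (deg)] terms;
# X-T2-T3-X entries match on the central bond
[dihedrals]
"X-C-N-X"   = [[2.5, 2, 180.0]]
"X-CT-CT-X" = [[0.1556, 3, 0.0]]
"X-CA-CA-X" = [[3.625, 2, 180.0]]
"X-CT-OH-X" = [[0.1667, 3, 0.0]]
"X-CT-N-X"  = [[0.0, 3, 0.0]]
"X-C-CT-X"  = [[0.0, 2, 180.0]]
"X-CA-CT-X" = [[0.0, 2, 0.0]]

# harmonic-cosine impropers keeping sp2 centers planar, keyed on the
# central atom's type: [k (kcal/mol), n, phi0 (deg)]
[impropers]
C  = [10.5, 2, 180.0]
CA = [1.1, 2, 180.0]
N  = [1.1, 2, 180.0]
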