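# Default dimensional parameter set (SI units).
# E is chosen so the bending modulus Bm = E*b^3/(12*(1-nu^2)) equals 4.5e-21 J;
# tau_k is chosen so the hydrodynamic/kinetic ratio tau = tau_mu/tau_k equals 15.
mu = 4e-2
E = 79101.5625
b = 8e-9
nu = 0.5
kappa = 1.2e-6
C0 = 2e14
C10 = 2e14
C20 = 4e14
l1 = 15e-9
l2 = 45e-9
D = 5e-13
tau_k = 0.0002469135802469136
L = 1e-5
kBT = 4.34e-21
gamma = 0.0
sigma_on = 0.2
sigma_off = 0.6
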