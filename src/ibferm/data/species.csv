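id,aliases,molar_mass,carbon_atoms,role,nadph_gen_per_mol,nadph_req_per_mol,redox_status
glucose,,180.2,6,substrate,2,,core
glycerol,,92.09,3,substrate,2,,core
butanol,BuOH;n-butanol,74.12,4,product,,4,core
isopropanol,IPA;2-propanol,60.10,3,product,,1,core
acetone,ACT,58.08,3,product,,0,core
acetic_acid,AA;acetate,60.05,2,product,,0,core
butyric_acid,BA;butyrate,88.11,4,product,,2,core
pdo_13,"1,3-PDO;1,3-propanediol;PDO",76.09,3,product,,1,extrapolated
ethanol,EtOH,46.07,2,product,,,extrapolated
sucrose,,342.30,12,substrate,,,extrapolated
xylose,,150.13,5,substrate,,,extrapolated
arabinose,,150.13,5,substrate,,,extrapolated
galactose,,180.16,6,substrate,,,extrapolated
mannose,,180.16,6,substrate,,,extrapolated
fructose,,180.16,6,substrate,,,extrapolated
cellobiose,,342.30,12,substrate,,,extrapolated
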