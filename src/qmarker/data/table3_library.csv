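id,name,rt_min,ion_formula,polarity,theoretical_mz,diagnostic_fragments,other_fragments,source_herbs,is_marker,anomalous
gluconic_acid,D-gluconic acid,0.53,C6H11O7,negative,195.0505,195.0504;177.0397;159.0292;129.0184,99.0077;87.0076,Liushenqu,false,
quinic_acid,Quinic acid,0.54,C7H11O6,negative,191.0556,191.0554;173.0449;127.0387,109.0286;93.0334;85.0283,Shanzha;Hongcha,false,
gallic_acid,Gallic acid,0.81,C7H5O5,negative,169.0137,169.0134;125.0234;107.0127,124.0156;97.0284;79.0178,Lianqiao;Hongcha,false,
protocatechuic_acid,Protocatechuic acid,1.65,C7H5O4,negative,153.0188,153.0184;109.0284;108.0206,110.0316;91.0177;81.0334,Chuanxiong;Chaihu;Lianqiao,false,
caffeoylquinic_acid_5,5-caffeoylquinic acid,1.73,C16H17O9,negative,353.0873,353.0866;191.0554;179.0340;173.0449;135.0442,161.0239;107.0489;93.0334;85.0283,Chaihu,false,
methyl_gallate,Methyl gallate,2.14,C8H7O5,negative,183.0293,183.0291;168.0056;139.0389;124.0156,140.0110;95.0128;89.9247,Hongcha,false,
caffeine,Caffeine,5.46,C8H11N4O2,positive,195.0882,195.0870;138.0658;123.0425;110.0713,108.0552;83.0607;69.0453;56.0502,Hongcha,true,
puerarin,Puerarin,7.92,C21H19O9,negative,415.1029,415.1035;295.0614;267.0663;253.0504;132.0208,277.0500;222.0680;209.0604;105.0334,Gancao;Maiya,false,
vicenin_2,Vicenin-2,8.43,C27H29O15,negative,593.1506,593.1511;325.0730;297.0768;283.0605,473.1089;383.0774;353.0669;117.0336,Hongcha,false,
schaftoside,Schaftoside,8.86,C26H27O14,negative,563.1401,563.1405;383.0769;353.0668;297.0767;117.0336,325.0721;135.0443;93.0334;79.0178,Chaihu,false,
myricetin_3_galactoside,Myricetin-3-O-galactoside,8.87,C21H19O13,negative,479.0826,479.0829;316.0221;287.0189;271.0249;242.0268,259.0247;151.0028;124.0155,Hongcha,false,
liquiritin,Liquiritin,9.05,C21H21O9,negative,417.1186,417.1195;255.0661;135.0078;119.0492,153.0185;108.0206;91.0178,Chaihu;Gancao,false,
vitexin,Vitexin,9.13,C21H19O10,negative,431.0978,431.0986;341.0061;311.0561;283.0613;135.0443,268.0373;117.0336,Hongcha;Shanzha,false,
acteoside,Acteoside,9.30,C29H35O15,negative,623.1976,623.1977;461.1666;161.0236;133.0285,179.0341;143.0339;115.0179,Houpo;Lianqiao,false,
scoparone,Scoparone,9.35,C11H11O4,positive,207.0652,207.0646;191.0331;163.0386;151.0750;146.0359,135.0437;107.0492,Chuanxiong,false,printed theoretical m/z follows the electron-corrected convention (plain formula mass 207.0657)
pinoresinol,(-)-Pinoresinol,9.36,C20H21O6,negative,357.1338,357.1339;151.0392;136.0156;121.0285,342.1114;108.0207,Lianqiao,false,
isovitexin,Isovitexin,9.39,C21H19O10,negative,431.0978,431.0981;341.0667;311.0556;283.0612,323.0559;269.0462;117.0337,Hongcha,false,
isoquercitrin,Isoquercitrin,9.51,C21H19O12,negative,463.0877,463.0884;300.0270;271.0244;255.0293,243.0291;227.0341;199.0390,Shanzha,false,
naringenin_7_glucoside,Naringenin-7-O-beta-D-glucoside,9.55,C21H21O10,negative,433.1135,433.1685;271.0615;151.0029;119.0493,177.0187;107.0128;93.0335,Shanzha,false,
rutin,Rutin,9.56,C27H29O16,negative,609.1456,609.1445;300.0277;271.0249;255.0297;243.0297,199.0393;171.0443;151.0026,Houpo;Chuanxiong;Lianqiao;Liushenqu,false,
naringin,Naringin,9.65,C27H31O14,negative,579.1714,579.1730;271.0611;151.0028;119.0492;107.0127,459.1143;227.0694,Zhishi;Chenpi,false,
rosmarinic_acid,Rosmarinic acid,9.76,C18H15O8,negative,359.0767,359.0780;197.0450;161.0235;133.0285,179.0341;135.0442;123.0442,Zisuye,false,
hesperidin,Hesperidin,9.79,C28H33O15,negative,609.1819,301.0717;164.0107;108.0207,609.1816;286.0483;242.0582;199.0396,Zhishi;Chenpi,true,
isochlorogenic_acid_a,Isochlorogenic acid A,9.84,C25H23O12,negative,515.1190,515.1226;353.0878;179.0342;135.0441,173.0447;93.0335,Qianghuo,false,
myricetin,Myricetin,9.84,C15H9O8,negative,317.0297,317.0304;151.0029;137.0235;109.0284,178.9979;119.0134,Hongcha,false,
astragalin,Astragalin,10.00,C21H19O11,negative,447.0927,447.0934;284.0330;255.0298;227.0346,327.0503;211.0395;199.0397;183.0444,Chuanxiong,false,
isorhamnetin_3_glucoside,Isorhamnetin-3-O-beta-D-glucoside,10.05,C22H21O12,negative,477.1033,477.1034;285.0401;271.0253;243.0295,314.0420;299.0193;257.0452;215.0343,Houpo,false,
saikosaponin_a,Saikosaponin A,10.38,C42H67O13,negative,779.4582,295.0605;185.0234;109.0285,159.0446;135.0442;123.0438,Chaihu,true,
daidzein,Daidzein,10.49,C15H9O4,negative,253.0501,253.0505;223.0395;208.0528;195.0454,180.0574;132.0207;91.0178,Zhishi,false,
quercetin,Quercetin,10.62,C15H9O7,negative,301.0348,301.0353;151.0028;121.0285;107.0128,178.9978;149.0234,Chaihu;Hongcha;Liushenqu,false,
dihydroxyflavone_74,"7,4'-dihydroxyflavone",10.71,C15H9O4,negative,253.0501,253.0504;223.0392;208.0530;135.0076;117.0336,153.0183;91.0177,Gancao,false,
naringenin,S-naringenin,10.87,C15H11O5,negative,271.0606,271.0613;151.0027;119.0492;107.0128,177.0182;165.0185,Zhishi;Chenpi,false,
naringenin_chalcone,Naringenin chalcone,10.88,C15H11O5,negative,271.0606,271.0613;187.0394;151.0028;119.0492,107.0128;93.0330,Chenpi,false,
luteolin,Luteolin,10.89,C15H9O6,negative,285.0399,285.0405;257.0444;217.0504;133.0285,199.0394;175.0393;151.0027,Shanzha,false,
hesperetin,S-hesperetin,11.08,C16H13O6,negative,301.0712,301.0715;164.0104;108.0206,151.0028;136.0156;80.0255,Zhishi;Qianghuo,false,
randaiol,Randaiol,11.09,C15H13O3,negative,241.0865,241.0867;223.0761;197.0965,157.0652;141.0700;95.0126,Houpo,false,
isoliquiritigenin,Isoliquiritigenin,11.55,C15H11O4,negative,255.0657,255.0603;135.0073;119.0493,153.0181;91.0177,Chaihu;Gancao,false,
platycodin_d,Platycodin D,11.63,C57H91O28,negative,1223.5697,1223.5709;391.3025,407.2975;143.0335;131.0340;113.0223,Jiegeng,false,
formononetin,Formononetin,11.79,C16H11O4,negative,267.0657,267.0664;252.0427;223.0396;167.0494;132.0206,208.0523;195.0446,Chaihu,false,
senkyunolide_a,S-senkyunolide A,12.00,C12H17O2,positive,193.1229,193.0491;147.1164;137.0593;105.0699,175.1111;95.0494;91.0545,Chuanxiong,true,
heptamethoxyflavone,"3,3',4',5,6,7,8-heptamethoxyflavone",12.49,C22H25O9,negative,433.1499,433.1479;403.1008;345.0589;165.0542,418.1250;205.0860;127.0388,Chenpi,false,
licoricesaponin_h2,Licoricesaponin H2,13.20,C42H61O16,negative,821.3960,821.3956;193.0344;113.0233,85.0284,Gancao,false,
hydroxyflavone_5,5-hydroxyflavone,13.26,C15H11O3,negative,239.0708,239.0694;165.0694;137.0229;103.0543,155.0336;129.0332,Zhisuzi,false,
magnolol,Magnolol,13.68,C18H17O2,negative,265.1229,265.1234;247.1125,245.0972;243.0811;223.0767,Houpo,true,
glycyrrhetinic_acid_18b,18beta-glycyrrhetinic acid,14.54,C30H45O4,negative,469.3318,469.3322;425.3415;355.2628,409.3105,Gancao,true,
linoleic_acid,Linoleic acid,15.42,C18H31O2,negative,279.2324,279.2330;261.2221,140.6269;111.0682;96.9586;83.0491;62.8557,Baizhi;Chaihu;Qianghuo;Chuanxiong,false,
palmitic_acid,Palmitic acid,15.54,C16H31O2,negative,255.2324,255.2329,247.5200;135.6278;87.0019;69.3279;61.1978,Houpo;Chuanxiong;Chaihu;Zhisuzi;Shanzha,false,
oleic_acid,Oleic acid,15.63,C18H33O2,negative,281.2486,281.2489;92.1643,201.4027;186.0976;112.4930;59.9085,Zhisuzi;Chaihu;Hongcha;Baizhi;Lianqiao,false,printed theoretical m/z follows the electron-corrected convention (plain formula mass 281.2481)
ethyl_palmitate,Ethyl palmitate,15.81,C18H35O2,negative,283.2637,283.2642,265.2533;186.1121;149.0329;125.7779;92.1631,Houpo;Hongcha,false,
ethyl_stearate,Ethyl stearate,16.35,C20H39O2,negative,311.2950,311.1689;183.0113;119.0492,133.0650;79.9561,Houpo,false,printed observed m/z 311.1683 is 407 ppm from the formula mass; the printed row is internally inconsistent
hypericin,Hypericin,16.50,C30H15O8,negative,503.0767,503.0771,459.0873;433.0717;405.0772,Lianqiao,false,
cholestenone,(+)-4-cholesten-3-one,16.70,C27H45O,positive,385.3470,385.3451;367.3355;255.2094;109.0650,123.0804;97.0651,Liushenqu,false,
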