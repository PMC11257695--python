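"""Monte-Carlo null quantiles of the dip statistic.

Uniform null, 10000 replicates per sample size, seeded
(20240901); regenerate with scripts/make_dip_table.py.
"""

N_GRID = [10, 15, 20, 30, 50, 80, 120, 200, 300, 500, 800, 1200, 2000]

PROBS = [
    0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08,
    0.09, 0.1, 0.11, 0.12, 0.13, 0.14, 0.15, 0.16,
    0.17, 0.18, 0.19, 0.2, 0.21, 0.22, 0.23, 0.24,
    0.25, 0.26, 0.27, 0.28, 0.29, 0.3, 0.31, 0.32,
    0.33, 0.34, 0.35, 0.36, 0.37, 0.38, 0.39, 0.4,
    0.41, 0.42, 0.43, 0.44, 0.45, 0.46, 0.47, 0.48,
    0.49, 0.5, 0.51, 0.52, 0.53, 0.54, 0.55, 0.56,
    0.57, 0.58, 0.59, 0.6, 0.61, 0.62, 0.63, 0.64,
    0.65, 0.66, 0.67, 0.68, 0.69, 0.7, 0.71, 0.72,
    0.73, 0.74, 0.75, 0.76, 0.77, 0.78, 0.79, 0.8,
    0.81, 0.82, 0.83, 0.84, 0.85, 0.86, 0.87, 0.88,
    0.89, 0.9, 0.91, 0.92, 0.93, 0.94, 0.95, 0.96,
    0.97, 0.98, 0.985, 0.99, 0.995, 0.998, 0.999,
]

QUANTILES = [
    [
        0.0607414, 0.0650136, 0.0679478, 0.0698467, 0.0717547, 0.0733151, 0.0744571, 0.0756423,
        0.0768735, 0.0778829, 0.0788748, 0.0796312, 0.0804134, 0.0810936, 0.0817246, 0.0824794,
        0.083227, 0.083878, 0.0845208, 0.0852459, 0.0858778, 0.086383, 0.0868738, 0.0873699,
        0.0878987, 0.0884179, 0.0889384, 0.0894197, 0.0898154, 0.0902302, 0.0906737, 0.0911462,
        0.0916069, 0.0920149, 0.0924568, 0.092829, 0.0931602, 0.0934855, 0.0938427, 0.094177,
        0.0946139, 0.0949538, 0.0952963, 0.095628, 0.0959389, 0.0962476, 0.0965911, 0.0969252,
        0.0972827, 0.0975857, 0.097954, 0.0983249, 0.0986428, 0.0989835, 0.09931, 0.0996649,
        0.0999839, 0.100664, 0.101343, 0.101995, 0.102677, 0.103431, 0.104243, 0.105099,
        0.105836, 0.106618, 0.107393, 0.108229, 0.109083, 0.110069, 0.110837, 0.111523,
        0.112314, 0.113222, 0.114115, 0.114907, 0.115901, 0.116843, 0.117752, 0.118801,
        0.11975, 0.120768, 0.121718, 0.122802, 0.123777, 0.124862, 0.125952, 0.127432,
        0.128775, 0.129953, 0.131613, 0.133174, 0.134807, 0.137211, 0.139572, 0.14209,
        0.145178, 0.149846, 0.154671, 0.159266, 0.166063, 0.174171, 0.178888,
    ],
    [
        0.0551091, 0.0572832, 0.0585623, 0.0598912, 0.0609381, 0.061775, 0.0624702, 0.0631263,
        0.0637218, 0.0642685, 0.0646999, 0.065134, 0.0655322, 0.0659107, 0.0663027, 0.0667482,
        0.067406, 0.0679667, 0.0685482, 0.0691277, 0.0696712, 0.0702241, 0.0708188, 0.0712309,
        0.0718081, 0.0723414, 0.0728321, 0.0733007, 0.0738393, 0.0742973, 0.0747397, 0.0751795,
        0.0757189, 0.0761873, 0.0766691, 0.0771752, 0.0775752, 0.0780076, 0.0784213, 0.0789276,
        0.0793958, 0.0798236, 0.0802982, 0.0807836, 0.0812352, 0.0816953, 0.0821167, 0.0825477,
        0.0830428, 0.0834258, 0.0838712, 0.0843843, 0.0847747, 0.0853068, 0.0857888, 0.0862859,
        0.0866776, 0.0871216, 0.0875836, 0.0880156, 0.0884917, 0.0890167, 0.0894485, 0.0899471,
        0.0904985, 0.0909882, 0.0915097, 0.092135, 0.0926454, 0.0931355, 0.0937402, 0.0942068,
        0.0947907, 0.0954649, 0.0961271, 0.0967716, 0.0974772, 0.0981372, 0.0989453, 0.0999293,
        0.100824, 0.101702, 0.102641, 0.103532, 0.104489, 0.105575, 0.106684, 0.108008,
        0.109169, 0.11061, 0.112132, 0.1136, 0.115383, 0.116967, 0.118471, 0.12106,
        0.12388, 0.128591, 0.13154, 0.134928, 0.140427, 0.147477, 0.155316,
    ],
    [
        0.0471172, 0.0487934, 0.0499239, 0.0512871, 0.0523665, 0.0533735, 0.054199, 0.0551249,
        0.0558959, 0.0566197, 0.0572353, 0.0579363, 0.0585398, 0.0590254, 0.0595643, 0.0600792,
        0.060607, 0.0610243, 0.0614639, 0.0619121, 0.0622701, 0.0627494, 0.0631837, 0.0635235,
        0.06393, 0.0643267, 0.0647576, 0.0651821, 0.0655015, 0.0659122, 0.066221, 0.0666137,
        0.0669816, 0.0673372, 0.0677105, 0.0680729, 0.068436, 0.0688262, 0.0691752, 0.0695833,
        0.0699574, 0.0703251, 0.0707084, 0.0710258, 0.0714354, 0.0717738, 0.0721325, 0.0725174,
        0.072925, 0.0733249, 0.073788, 0.0741946, 0.0746781, 0.0750578, 0.0754862, 0.0759018,
        0.0763374, 0.0767699, 0.0772899, 0.0777266, 0.0782056, 0.0786454, 0.0790746, 0.079504,
        0.0799821, 0.0805045, 0.0809111, 0.0815106, 0.0820334, 0.082482, 0.0829513, 0.0835062,
        0.084039, 0.0845893, 0.0851146, 0.0857053, 0.086331, 0.0869511, 0.0875706, 0.088167,
        0.088947, 0.0897915, 0.0905329, 0.0912862, 0.092127, 0.0931222, 0.0940248, 0.0948777,
        0.0959745, 0.0969723, 0.0981668, 0.0996061, 0.100796, 0.102601, 0.104795, 0.107044,
        0.110409, 0.113794, 0.116209, 0.12007, 0.125599, 0.131545, 0.135127,
    ],
    [
        0.0395185, 0.0413943, 0.0427226, 0.043633, 0.044342, 0.0450854, 0.0456462, 0.0462332,
        0.046779, 0.0473452, 0.0478107, 0.0482814, 0.0487484, 0.0492957, 0.0497006, 0.0500463,
        0.0504398, 0.0508171, 0.0511573, 0.0516275, 0.0520803, 0.0524252, 0.0527547, 0.0531036,
        0.0534553, 0.0537902, 0.0540923, 0.0544093, 0.0547368, 0.0549993, 0.0553245, 0.0556654,
        0.0560454, 0.0563456, 0.0566288, 0.0569138, 0.0572353, 0.0575747, 0.0578668, 0.0581746,
        0.0584743, 0.0587351, 0.0590472, 0.0593681, 0.0596482, 0.0599834, 0.0602667, 0.0606494,
        0.0609595, 0.0612904, 0.0615873, 0.0619087, 0.0621901, 0.0625088, 0.0628557, 0.0631976,
        0.0635595, 0.0638919, 0.0642299, 0.0645585, 0.064947, 0.0653135, 0.065709, 0.0660838,
        0.0665069, 0.0669801, 0.0673886, 0.0677943, 0.0682077, 0.0685819, 0.0689949, 0.069454,
        0.0699223, 0.0704073, 0.0708777, 0.0713601, 0.071893, 0.0723793, 0.0728374, 0.073396,
        0.0739906, 0.0745633, 0.0752502, 0.0759926, 0.0767681, 0.0775811, 0.0785075, 0.0793167,
        0.0802143, 0.0810081, 0.0820576, 0.0833006, 0.0849815, 0.0864509, 0.0881073, 0.0901778,
        0.0927007, 0.0964406, 0.0991002, 0.102006, 0.107523, 0.113814, 0.117638,
    ],
    [
        0.031294, 0.0327072, 0.0336837, 0.0346669, 0.0354164, 0.0360519, 0.036512, 0.0369196,
        0.0373284, 0.0377318, 0.0380876, 0.0384216, 0.0387698, 0.0391458, 0.0394972, 0.0398691,
        0.0401996, 0.0404857, 0.0408085, 0.041111, 0.0414304, 0.0417172, 0.0419662, 0.0422396,
        0.0425392, 0.0428052, 0.0430391, 0.0432538, 0.0434664, 0.043704, 0.0439756, 0.044217,
        0.0444552, 0.0447062, 0.0449805, 0.0452206, 0.0454338, 0.0456661, 0.0459284, 0.0461832,
        0.0464256, 0.0466747, 0.0469558, 0.0472014, 0.0474773, 0.0476967, 0.0479803, 0.0482483,
        0.0485082, 0.0487543, 0.0490087, 0.0492689, 0.0494848, 0.0496998, 0.0499772, 0.0502547,
        0.0505185, 0.050811, 0.0511122, 0.0514076, 0.0516843, 0.0519485, 0.0522378, 0.0525738,
        0.052841, 0.0532074, 0.053576, 0.0539248, 0.0542247, 0.0545857, 0.0549066, 0.0552405,
        0.0555639, 0.055992, 0.0564024, 0.0567863, 0.0572511, 0.0577067, 0.0580974, 0.05855,
        0.0589668, 0.0595146, 0.0600621, 0.0605924, 0.061171, 0.061893, 0.062519, 0.0632184,
        0.064019, 0.0647986, 0.0655976, 0.0666595, 0.0674981, 0.068813, 0.0701118, 0.071727,
        0.0737004, 0.076203, 0.0778858, 0.0807615, 0.0844494, 0.0908075, 0.0944726,
    ],
    [
        0.0255053, 0.0267037, 0.0275028, 0.0281686, 0.028697, 0.0291552, 0.0295166, 0.0299362,
        0.0302551, 0.0305139, 0.0308259, 0.0311274, 0.031388, 0.0316562, 0.0319223, 0.0321767,
        0.0324847, 0.0327534, 0.0329886, 0.0332118, 0.0334305, 0.0336464, 0.0338951, 0.0341224,
        0.0343359, 0.0345839, 0.0347763, 0.034986, 0.0351772, 0.0353511, 0.0356051, 0.0357959,
        0.0360143, 0.0362219, 0.0364063, 0.0366402, 0.0368578, 0.0370706, 0.0372398, 0.0374213,
        0.0376213, 0.0378457, 0.038059, 0.0382677, 0.0384655, 0.0386918, 0.038909, 0.0391272,
        0.0393408, 0.039558, 0.0397418, 0.0399072, 0.0401275, 0.0403461, 0.0405497, 0.0407922,
        0.0410093, 0.0412223, 0.0414609, 0.0416583, 0.041907, 0.0421555, 0.0423988, 0.0426822,
        0.0429418, 0.0432124, 0.0434667, 0.0437348, 0.0439963, 0.0442991, 0.0445958, 0.0448584,
        0.0451359, 0.0454078, 0.0457421, 0.0460708, 0.0463715, 0.0467245, 0.0470591, 0.0474121,
        0.0477328, 0.0481499, 0.0486122, 0.0490819, 0.0495287, 0.0500765, 0.0505323, 0.0510675,
        0.0516057, 0.0521903, 0.0528241, 0.053621, 0.0544712, 0.0555303, 0.0565659, 0.0578784,
        0.0595128, 0.0617976, 0.0634256, 0.0655386, 0.0681225, 0.0727187, 0.0762302,
    ],
    [
        0.0207239, 0.0217962, 0.0226237, 0.0232249, 0.0236557, 0.0240113, 0.0243142, 0.0246255,
        0.0248954, 0.0251807, 0.0254718, 0.0257343, 0.0259767, 0.0261955, 0.0263713, 0.0265679,
        0.0267759, 0.0269686, 0.027196, 0.0273906, 0.0275896, 0.0277461, 0.0279505, 0.028113,
        0.028292, 0.0284645, 0.0286224, 0.0287892, 0.028967, 0.0291541, 0.02935, 0.0295348,
        0.029732, 0.0298735, 0.0300315, 0.03019, 0.0303519, 0.0305308, 0.0306741, 0.0308335,
        0.0310247, 0.0311579, 0.0313248, 0.0314832, 0.0316569, 0.0318439, 0.0319924, 0.0321602,
        0.0323297, 0.0325122, 0.0326915, 0.0328753, 0.0330354, 0.0331994, 0.0333941, 0.0335889,
        0.0337857, 0.0339573, 0.0341727, 0.0343862, 0.0345892, 0.0348114, 0.0350163, 0.0352223,
        0.0354551, 0.035683, 0.0359432, 0.036142, 0.03633, 0.0365252, 0.0367761, 0.0370038,
        0.0372361, 0.0375425, 0.0378053, 0.0380028, 0.0382968, 0.0386087, 0.0388411, 0.039152,
        0.0395226, 0.0398881, 0.0402519, 0.0406427, 0.040964, 0.0412995, 0.0417452, 0.0422514,
        0.0428074, 0.0433905, 0.0439487, 0.0445034, 0.0453645, 0.0461632, 0.047109, 0.0481207,
        0.0493225, 0.0511973, 0.0526279, 0.0541221, 0.0570856, 0.0608164, 0.0632749,
    ],
    [
        0.0164575, 0.0173112, 0.0177703, 0.0182148, 0.018564, 0.0188297, 0.019083, 0.0193224,
        0.0195618, 0.0198017, 0.0200034, 0.0202211, 0.0204161, 0.0205672, 0.0207484, 0.0209341,
        0.0211075, 0.0212424, 0.0214355, 0.0215744, 0.0217246, 0.0218666, 0.0219992, 0.0221372,
        0.0222792, 0.0224041, 0.0225289, 0.0226349, 0.0227735, 0.0229084, 0.0230504, 0.0231872,
        0.0233227, 0.0234463, 0.0235741, 0.0237036, 0.0238465, 0.0239906, 0.0241085, 0.02425,
        0.0243649, 0.0245113, 0.0246452, 0.0247635, 0.0249137, 0.0250469, 0.025169, 0.0253109,
        0.0254426, 0.025604, 0.0257232, 0.0258742, 0.0260189, 0.0261453, 0.0262921, 0.0264008,
        0.0265341, 0.026674, 0.0268543, 0.0270222, 0.0271772, 0.0273601, 0.0275129, 0.0276834,
        0.0278392, 0.0280266, 0.0282038, 0.0283593, 0.0285319, 0.0286886, 0.0288713, 0.0290486,
        0.0292514, 0.0294283, 0.0296832, 0.029877, 0.0300959, 0.0303501, 0.0305724, 0.0308222,
        0.0310793, 0.0313463, 0.0315951, 0.0319016, 0.0322465, 0.0325911, 0.032871, 0.0332503,
        0.0336314, 0.0340366, 0.0345037, 0.0350153, 0.0356518, 0.0362428, 0.0368456, 0.037874,
        0.0388184, 0.0402726, 0.0413403, 0.0423908, 0.0447181, 0.0475429, 0.050369,
    ],
    [
        0.0134546, 0.014111, 0.0145358, 0.0149268, 0.0151761, 0.0154405, 0.0156812, 0.0158869,
        0.016101, 0.0162829, 0.0164297, 0.0166051, 0.0167463, 0.016907, 0.017042, 0.0171912,
        0.0173132, 0.0174261, 0.0175548, 0.0176735, 0.0177995, 0.0179194, 0.0180438, 0.018139,
        0.0182483, 0.0183594, 0.0184799, 0.0185972, 0.0186997, 0.0188261, 0.0189368, 0.019046,
        0.0191417, 0.0192501, 0.0193738, 0.0195048, 0.0196041, 0.0197116, 0.0198233, 0.019925,
        0.020042, 0.0201278, 0.0202427, 0.0203429, 0.0204484, 0.0205487, 0.020657, 0.0207796,
        0.0208983, 0.0210044, 0.0211345, 0.0212452, 0.0213677, 0.021466, 0.0215795, 0.0216964,
        0.0218294, 0.0219417, 0.0220778, 0.0221943, 0.0223235, 0.0224452, 0.0225778, 0.0227174,
        0.0228507, 0.0229789, 0.0231124, 0.0232258, 0.0233803, 0.0235401, 0.0236854, 0.0238274,
        0.0239986, 0.0241895, 0.0243939, 0.0245652, 0.0247381, 0.0249048, 0.0251418, 0.0253275,
        0.025519, 0.0257436, 0.0259752, 0.0261885, 0.0264198, 0.0266714, 0.0270204, 0.027329,
        0.0276253, 0.028014, 0.0283294, 0.0287282, 0.0291923, 0.0297105, 0.0303318, 0.0311248,
        0.032174, 0.0332528, 0.0340661, 0.0350986, 0.0365219, 0.0387243, 0.0407398,
    ],
    [
        0.0106257, 0.0111149, 0.0114946, 0.0117623, 0.011984, 0.0121851, 0.0123529, 0.0124981,
        0.0126475, 0.0128075, 0.0129476, 0.0130614, 0.0131797, 0.0132727, 0.0133828, 0.0134865,
        0.0135858, 0.0136986, 0.0137894, 0.0138985, 0.0139939, 0.0140994, 0.0141813, 0.0142642,
        0.0143631, 0.0144487, 0.0145204, 0.0146147, 0.0147018, 0.0147898, 0.0148668, 0.0149563,
        0.0150453, 0.0151419, 0.0152245, 0.0153199, 0.0154, 0.015473, 0.0155573, 0.0156384,
        0.015714, 0.0158058, 0.0158813, 0.0159723, 0.0160468, 0.0161285, 0.0162062, 0.0162902,
        0.0163786, 0.0164666, 0.0165494, 0.0166451, 0.0167488, 0.0168218, 0.0169135, 0.0170137,
        0.017117, 0.0172107, 0.0173121, 0.0174094, 0.0175088, 0.0176025, 0.0176968, 0.0177952,
        0.0178965, 0.0179958, 0.0180919, 0.018211, 0.0183207, 0.0184434, 0.0185534, 0.0186652,
        0.0188153, 0.0189349, 0.0190613, 0.0191847, 0.0193251, 0.0194553, 0.0196349, 0.0197901,
        0.0199567, 0.0201594, 0.0203459, 0.0205523, 0.0207061, 0.0209062, 0.021136, 0.0213762,
        0.0216281, 0.0218864, 0.0222063, 0.0225089, 0.022805, 0.0232416, 0.0236858, 0.0241908,
        0.0249403, 0.025814, 0.0264328, 0.0274045, 0.0289205, 0.0308947, 0.0324335,
    ],
    [
        0.00848268, 0.00886573, 0.0091111, 0.00934088, 0.00950939, 0.00965119, 0.00977029, 0.00992219,
        0.0100543, 0.0101719, 0.010299, 0.0104008, 0.0104855, 0.0105614, 0.0106385, 0.0107187,
        0.0107875, 0.0108735, 0.0109577, 0.0110384, 0.0111203, 0.0111834, 0.0112623, 0.0113387,
        0.0114199, 0.0114832, 0.0115378, 0.011602, 0.0116654, 0.0117382, 0.0118075, 0.0118627,
        0.0119283, 0.0119934, 0.0120546, 0.01212, 0.0121908, 0.0122594, 0.0123217, 0.0123912,
        0.0124577, 0.0125341, 0.0126038, 0.0126703, 0.0127446, 0.0128172, 0.0128825, 0.0129518,
        0.0130188, 0.0130841, 0.0131479, 0.0132275, 0.0133056, 0.0133711, 0.0134384, 0.0135129,
        0.0135836, 0.0136518, 0.0137206, 0.013799, 0.013889, 0.0139511, 0.014025, 0.0141081,
        0.0141936, 0.0142897, 0.0143938, 0.0144793, 0.0145635, 0.0146525, 0.0147397, 0.0148402,
        0.0149357, 0.0150283, 0.0151462, 0.0152707, 0.0153743, 0.0154832, 0.0156045, 0.0157177,
        0.0158531, 0.0159734, 0.0161001, 0.01626, 0.0163928, 0.0165457, 0.0166921, 0.0168921,
        0.0170759, 0.0172913, 0.0175546, 0.0178052, 0.0180886, 0.018419, 0.0188279, 0.0192151,
        0.0197228, 0.0205115, 0.0210647, 0.0218054, 0.0232354, 0.0246326, 0.0257878,
    ],
    [
        0.00691135, 0.00723392, 0.00743447, 0.00760169, 0.00774697, 0.00784563, 0.00795299, 0.00807511,
        0.00816911, 0.00827045, 0.00835529, 0.00843477, 0.00851147, 0.00859407, 0.00866152, 0.00873075,
        0.00879353, 0.00886739, 0.00893865, 0.00901179, 0.0090713, 0.00912932, 0.00918927, 0.00924501,
        0.00929815, 0.00935624, 0.0094204, 0.00947235, 0.00953518, 0.0095832, 0.00963653, 0.00970451,
        0.00975813, 0.00981398, 0.00987528, 0.00992877, 0.0099845, 0.0100435, 0.0100996, 0.0101507,
        0.0102082, 0.0102726, 0.0103306, 0.0103859, 0.0104407, 0.0105063, 0.0105556, 0.0106135,
        0.0106689, 0.010735, 0.0107939, 0.0108606, 0.010922, 0.0109861, 0.0110441, 0.011098,
        0.0111603, 0.0112157, 0.0112789, 0.0113448, 0.0114003, 0.0114696, 0.0115388, 0.0116049,
        0.0116748, 0.0117503, 0.0118259, 0.0119059, 0.0119759, 0.0120533, 0.0121345, 0.0122059,
        0.0122998, 0.0123915, 0.0124746, 0.0125672, 0.0126575, 0.0127594, 0.0128464, 0.0129562,
        0.0130692, 0.0131914, 0.0133163, 0.0134458, 0.013569, 0.0136975, 0.0138369, 0.013987,
        0.0141599, 0.0143306, 0.0145162, 0.0147307, 0.014989, 0.0152137, 0.0154778, 0.0157821,
        0.0162937, 0.0169575, 0.0174191, 0.0180754, 0.0189092, 0.0199156, 0.0204944,
    ],
    [
        0.00539287, 0.00564983, 0.00583458, 0.00595165, 0.00607897, 0.0061785, 0.00626488, 0.00634988,
        0.006421, 0.0064965, 0.00655616, 0.00661626, 0.00667641, 0.00673019, 0.00678284, 0.00683991,
        0.00689302, 0.00694687, 0.00699342, 0.00703334, 0.00708122, 0.00713284, 0.00718559, 0.00723269,
        0.00728052, 0.00732349, 0.00736874, 0.00740508, 0.00744688, 0.00749224, 0.00753633, 0.00757207,
        0.00761506, 0.00765079, 0.00769208, 0.00773837, 0.0077828, 0.00782415, 0.00786226, 0.00791207,
        0.00795664, 0.00800139, 0.00804505, 0.00809119, 0.00813477, 0.00817187, 0.00821567, 0.00825784,
        0.00830034, 0.00834507, 0.00838445, 0.00842535, 0.00847277, 0.00851669, 0.00857032, 0.00862226,
        0.00867193, 0.0087201, 0.00876823, 0.00882385, 0.00887214, 0.00892443, 0.00897451, 0.00903563,
        0.00908435, 0.00912704, 0.00919081, 0.00924836, 0.00930304, 0.0093618, 0.0094378, 0.00949398,
        0.00955233, 0.00963017, 0.00969626, 0.00976857, 0.00982906, 0.00989815, 0.00995708, 0.0100354,
        0.0101221, 0.010211, 0.0102963, 0.0104004, 0.0104925, 0.0106167, 0.0107313, 0.0108586,
        0.0109929, 0.0111405, 0.0112913, 0.0114532, 0.0116198, 0.011851, 0.0120123, 0.0123062,
        0.0126572, 0.0130559, 0.0134218, 0.0138286, 0.0146293, 0.0158257, 0.0163319,
    ],
]
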