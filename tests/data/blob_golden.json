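{"description": "synthetic golden regression fixture: predictions and scores of a small deep RBF net fitted on two separable blobs", "config": {"hidden_layer_sizes": [4, 3], "max_epochs": 200, "pretrain_epochs": 10, "refresh_output_centers": true, "seed": 5}, "query_points": [[0.14547704146814588, 0.36191837642874675, -0.08165385388507176, 0.30890249836462963, 0.5951747792028866, -0.60099107770612, 0.5013876434107553, 0.3729366267188042], [0.6319668320659578, -0.18869411371798162, -0.014822749370816296, 0.04101069227431101, -0.23394468445413474, 0.49851638782629343, 0.11400307496431233, -0.48681901567258534], [0.13055009003581813, -0.5202952332064521, -0.7652720049521969, -0.5077590410244056, 0.01237479192914063, 0.059443780815567435, -0.050563074622795606, 0.26790948256279434], [0.9448489836377898, -0.5504125098149131, 0.211782184386968, 0.13746828173125547, -0.5806774647503647, -0.24382601083702768, 0.10185311757699055, 0.017535211981255742], [-0.4050836394144017, 0.37746370093127457, 0.11926939436695963, 0.3149026736370945, 0.778603538520743, -0.6179536579299969, 0.4842089459301472, 0.23426557875179158], [-0.42382772192160123, -0.026130953368919872, -0.20128142590093293, -0.5691075591612945, 0.3947845899913832, -0.3752410508639595, -0.9900206700255878, 0.40168322215808966], [-0.23640195709986117, 0.18130586782340466, 0.10086749734425404, -0.1488613652295305, -0.18507202114136875, -1.2323394403868315, -0.1992433476723126, -0.5537718014612409], [0.24596786464956394, -0.3800654276467636, -0.3185502851196386, 0.047417347225489216, -0.5605568928420933, -0.34651942260836677, -0.23773965237459688, 0.19483201155355437], [-0.7070655157852656, 0.3713368350681677, -0.07090295467786537, -0.24562280337020248, 0.16536772422185878, 0.4909200253236833, 0.5586691589699381, -0.5087516634358965], [0.6518766030310094, 0.01541207035145399, 0.634737189728973, -0.5167209890581579, -0.08497138944845002, -0.055894132777577286, -0.6194876703754222, -0.22325464656839558], [6.004253284980816, -0.22497459504111056, -0.40827557510108087, 0.04494749216689697, 0.020736038369963482, 0.3559934271979833, -0.046330661921112036, 0.37802353675650835], [5.906605409232868, 0.8269536677203535, 0.013346130855707511, 0.3736968922949934, 0.22833099440326482, -0.6142891749139519, 0.5485921207103757, -0.1708691047010133], [6.492900767241067, -0.9532289435027314, -0.8812931617200921, -0.9548378002052285, -0.8558445915183063, -0.16175139751771986, 0.013366715994613873, -0.4562475198466968], [5.859067807465768, -0.3099104374731325, 0.3931170426655032, 0.37911737063173384, 0.17529570246620862, 0.346939237126242, 0.8753836190218947, 0.3470193419902013], [5.273398101439781, -0.07847082652555519, -0.12223662595101588, 0.42969752924976723, 0.26149266065578136, 0.45183039843914075, -0.7394532821874122, 0.71536248737804], [5.950008226976316, 0.49945522525424846, 0.2614586854433309, -0.4133863040020553, -0.383228867423491, 0.31823880971617047, 0.5844607878310549, -0.4310842964015693], [5.452983369519544, -1.0001602422669826, -0.4472851717081448, -0.35575083211179, -0.13453282459944513, 0.30882699339261716, -0.23429778229293627, -0.5446674036092838], [5.817342736760502, -0.033909033798167905, 0.07639635863768653, 0.06842457572852235, -0.08527657371766259, 0.27229082957344486, -0.1439879742337699, -0.5162479769814308], [5.913483284018904, 0.915944892638354, -0.4055710424644278, 1.2093768947539076, -0.24990422291161743, 0.3524893337172858, -0.7955202244967292, -0.050780504349697574], [6.709319861885099, -0.5790939036834736, -0.3582897409466366, 0.1559215060783419, 0.17316460196153424, -0.7311479811985864, -0.6204856918298254, 0.14146667422856155]], "labels": ["non_DM", "non_DM", "non_DM", "non_DM", "non_DM", "non_DM", "non_DM", "non_DM", "non_DM", "non_DM", "DM", "DM", "DM", "DM", "DM", "DM", "DM", "DM", "DM", "DM"], "scores": [[0.9996146980156624, 0.012617748552788056], [0.9999401267309556, 0.013559858528690474], [0.9997466386316032, 0.012804777983059209], [0.9902924153881895, 0.02034613551892323], [0.999844216413731, 0.012998805051338063], [0.9999585015030719, 0.01354439387469016], [0.9999085013802871, 0.014010890194734173], [0.9995973793402397, 0.012578946480292905], [0.9999440938596165, 0.01368686805693999], [0.9998082709224076, 0.014278106360448083], [0.012787281926907743, 0.9997390014181283], [0.013253557793150064, 0.9999429734650999], [0.017981734193243858, 0.9954880348309529], [0.012168526823367179, 0.9992154925386092], [0.017204655931323438, 0.9968415621089904], [0.012621246911819923, 0.9996280537232736], [0.01575313610724279, 0.9988125615101042], [0.012598452840221794, 0.9996111810485626], [0.013611049587440176, 0.9999987143540543], [0.012494820014508558, 0.9995293725883447]]}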